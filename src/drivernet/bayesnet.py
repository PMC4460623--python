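"""Per-module directed structure learning.

Discrete data (equal-frequency bins), BDe marginal-likelihood scoring,
mutual-information candidate-parent restriction, greedy hill climbing with
add/remove/reverse/swap-parent moves, three tie-break-randomized runs, and a
>= 2-of-3 consensus.  The final mixed network keeps seed edges plus consensus
edges confirmed by a co-expression link; remaining co-expression links stay
undirected.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .motifs import DirectedSeedEdge
from .network import Edge, RegulatoryNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Discretization


def discretize(expr: pd.DataFrame, r: int = 3) -> pd.DataFrame:
    """Equal-frequency binning per gene into labels 0..r-1.

    Ties are broken by (value, sample position) via a stable argsort, so the
    output is deterministic across runs.  A gene with fewer distinct values
    than bins effectively uses fewer labels (constant genes are all-0).
    """
    if r < 2:
        raise ValueError("arity r must be >= 2")
    out = np.empty(expr.shape, dtype=np.int64)
    n = expr.shape[1]
    for i, (_, row) in enumerate(expr.iterrows()):
        vals = row.to_numpy(dtype=float)
        if np.unique(vals).size == 1:
            warnings.warn(f"discretize: constant gene {expr.index[i]}", stacklevel=2)
            out[i] = 0
            continue
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        out[i] = (ranks * r) // n
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# BDe score


@dataclass
class BDeParams:
    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("equivalent sample size must be > 0")


def bde_family_score(
    node: str,
    parents: tuple[str, ...],
    data: pd.DataFrame,
    ess: float = 1.0,
    arity: int | None = None,
) -> float:
    """Log BDe family contribution for one node given its parent set.

    score = sum_j [ lnG(a_ij) - lnG(a_ij + N_ij)
                    + sum_k ( lnG(a_ijk + N_ijk) - lnG(a_ijk) ) ]
    with a_ijk = ess/(q_i r_i), a_ij = ess/q_i, q_i = prod of parent arities.
    """
    values = data.loc[node].to_numpy()
    r_i = int(arity if arity is not None else data.to_numpy().max() + 1)
    if data.shape[1] == 0:
        return 0.0
    if parents:
        pmat = data.loc[list(parents)].to_numpy()
        arities = [r_i] * len(parents)
        q_i = int(np.prod(arities))
        # mixed-radix parent configuration index
        j_index = np.zeros(data.shape[1], dtype=np.int64)
        for row, a in zip(pmat, arities):
            j_index = j_index * a + row
    else:
        q_i = 1
        j_index = np.zeros(data.shape[1], dtype=np.int64)
    counts = np.zeros((q_i, r_i))
    np.add.at(counts, (j_index, values), 1.0)
    a_ijk = ess / (q_i * r_i)
    a_ij = ess / q_i
    n_ij = counts.sum(axis=1)
    score = (
        gammaln(a_ij) * q_i
        - gammaln(a_ij + n_ij).sum()
        + gammaln(a_ijk + counts).sum()
        - gammaln(a_ijk) * q_i * r_i
    )
    return float(score)


def bde_total_score(
    edges: set[tuple[str, str]],
    data: pd.DataFrame,
    ess: float = 1.0,
    arity: int | None = None,
) -> float:
    """Total BDe score = sum of family scores (decomposable)."""
    parents: dict[str, list[str]] = {n: [] for n in data.index}
    for u, v in edges:
        parents[v].append(u)
    return sum(
        bde_family_score(n, tuple(sorted(parents[n])), data, ess, arity)
        for n in data.index
    )


# ---------------------------------------------------------------------------
# Sparse candidates


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (bits) between two discrete label vectors."""
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def sparse_candidates(
    data: pd.DataFrame,
    k: int,
    seed_edges: set[tuple[str, str]] | None = None,
) -> dict[str, set[str]]:
    """Top-k candidate parents per node by mutual information.

    Seed-edge parents are always included on top of the MI picks.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = list(data.index)
    mat = data.to_numpy()
    n = len(nodes)
    mi = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mi[i, j] = mi[j, i] = mutual_information(mat[i], mat[j])
    cands: dict[str, set[str]] = {}
    for i, node in enumerate(nodes):
        others = [j for j in range(n) if j != i]
        # sort by MI descending; node order breaks ties deterministically
        others.sort(key=lambda j: (-mi[i, j], nodes[j]))
        cands[node] = {nodes[j] for j in others[: min(k, len(others))]}
    for u, v in seed_edges or ():
        if u in cands and v in cands:
            cands[v].add(u)
    return cands


# ---------------------------------------------------------------------------
# Hill climbing


@dataclass
class LearnedDag:
    nodes: list[str]
    edges: set[tuple[str, str]]
    score: float
    run_seed: int
    converged: bool = True
    score_trace: list[float] = field(default_factory=list)


def _creates_cycle(edges_by_child: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u -> v close a cycle? (DFS for a path v ->* u)."""
    children: dict[str, set[str]] = {}
    for child, pars in edges_by_child.items():
        for p in pars:
            children.setdefault(p, set()).add(child)
    stack, seen = [v], set()
    while stack:
        node = stack.pop()
        if node == u:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(children.get(node, ()))
    return False


def _break_seed_cycles(
    edges: set[tuple[str, str]], support: dict[tuple[str, str], float] | None = None
) -> set[tuple[str, str]]:
    """Drop lowest-support edges until the seed graph is acyclic."""
    import networkx as nx

    g = nx.DiGraph(list(edges))
    kept = set(edges)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return kept
        cyc_edges = [(u, v) for u, v, *_ in cycle]
        worst = min(cyc_edges, key=lambda e: ((support or {}).get(e, 0.0), e))
        logger.warning("seed cycle broken by dropping %s -> %s", *worst)
        kept.discard(worst)
        g.remove_edge(*worst)


def learn_structure(
    data: pd.DataFrame,
    seed_edges: set[tuple[str, str]],
    candidates: dict[str, set[str]],
    run_seed: int = 0,
    ess: float = 1.0,
    max_parents: int = 4,
    max_iter: int = 500,
    arity: int | None = None,
) -> LearnedDag:
    """Greedy hill climbing from the seed graph under the BDe score.

    Moves: add edge, remove edge, reverse edge, swap parent.  Legality: the
    new parent must be in the child's candidate set, the graph stays acyclic,
    parent sets stay <= max_parents, no self loops.  ``run_seed`` only
    shuffles tie order among equal-score moves.
    """
    nodes = list(data.index)
    r_i = int(arity if arity is not None else data.to_numpy().max() + 1)
    rng = np.random.default_rng(run_seed)
    seed_edges = {(u, v) for u, v in seed_edges if u != v and u in candidates and v in candidates}
    seed_edges = _break_seed_cycles(seed_edges)
    parents: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in seed_edges:
        parents[v].add(u)

    fam_cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(node: str, pars: set[str]) -> float:
        key = (node, tuple(sorted(pars)))
        if key not in fam_cache:
            fam_cache[key] = bde_family_score(node, key[1], data, ess, r_i)
        return fam_cache[key]

    total = sum(family(n, parents[n]) for n in nodes)
    trace = [total]
    converged = False
    for _ in range(max_iter):
        moves: list[tuple[float, int, str, tuple]] = []

        def consider(delta: float, kind: str, payload: tuple) -> None:
            moves.append((delta, int(rng.integers(1 << 30)), kind, payload))

        for v in nodes:
            pv = parents[v]
            base_v = family(v, pv)
            # add u -> v
            for u in candidates[v] - pv:
                if u == v or len(pv) >= max_parents:
                    continue
                if _creates_cycle(parents, u, v):
                    continue
                delta = family(v, pv | {u}) - base_v
                consider(delta, "add", (u, v))
            # remove / reverse / swap around existing parents of v
            for u in sorted(pv):
                delta_rm = family(v, pv - {u}) - base_v
                consider(delta_rm, "remove", (u, v))
                # reverse u -> v  =>  v -> u
                pu = parents[u]
                if (
                    v in candidates[u]
                    and len(pu) < max_parents
                ):
                    tmp = {n: set(p) for n, p in parents.items()}
                    tmp[v].discard(u)
                    if not _creates_cycle(tmp, v, u):
                        delta = (
                            delta_rm
                            + family(u, pu | {v})
                            - family(u, pu)
                        )
                        consider(delta, "reverse", (u, v))
                # swap parent u for candidate w
                for w in candidates[v] - pv - {u, v}:
                    tmp = {n: set(p) for n, p in parents.items()}
                    tmp[v].discard(u)
                    if _creates_cycle(tmp, w, v):
                        continue
                    delta = family(v, (pv - {u}) | {w}) - base_v
                    consider(delta, "swap", (u, w, v))
        if not moves:
            converged = True
            break
        moves.sort(key=lambda m: (-m[0], m[1]))
        best_delta, _, kind, payload = moves[0]
        if best_delta <= 1e-12:
            converged = True
            break
        if kind == "add":
            u, v = payload
            parents[v].add(u)
        elif kind == "remove":
            u, v = payload
            parents[v].discard(u)
        elif kind == "reverse":
            u, v = payload
            parents[v].discard(u)
            parents[u].add(v)
        else:  # swap
            u, w, v = payload
            parents[v].discard(u)
            parents[v].add(w)
        total += best_delta
        trace.append(total)
    else:
        warnings.warn("learn_structure: max_iter reached before convergence",
                      stacklevel=2)
    edges = {(u, v) for v, pv in parents.items() for u in pv}
    return LearnedDag(nodes=nodes, edges=edges, score=total, run_seed=run_seed,
                      converged=converged, score_trace=trace)


def consensus(
    dags: list[LearnedDag], min_support: int = 2
) -> dict[tuple[str, str], float]:
    """Directed edges appearing in >= min_support runs, with support/n_runs."""
    if not dags:
        return {}
    node_set = set(dags[0].nodes)
    for dag in dags[1:]:
        if set(dag.nodes) != node_set:
            raise ValueError("consensus: node sets differ across runs")
    counts: dict[tuple[str, str], int] = {}
    for dag in dags:
        for edge in dag.edges:
            counts[edge] = counts.get(edge, 0) + 1
    n = len(dags)
    return {e: c / n for e, c in counts.items() if c >= min_support}


def learn_consensus(
    data: pd.DataFrame,
    seed_edges: set[tuple[str, str]],
    candidates: dict[str, set[str]],
    n_runs: int = 3,
    min_support: int = 2,
    base_seed: int = 0,
    **kwargs,
) -> tuple[dict[tuple[str, str], float], list[LearnedDag]]:
    """Run hill climbing ``n_runs`` times (tie-break seeds differ) and keep
    edges at >= min_support/n_runs confidence."""
    seeds = np.random.SeedSequence(base_seed).spawn(n_runs)
    dags = [
        learn_structure(data, seed_edges, candidates,
                        run_seed=int(s.generate_state(1)[0]), **kwargs)
        for s in seeds
    ]
    return consensus(dags, min_support), dags


# ---------------------------------------------------------------------------
# Assembly


def assemble_grn(
    seed_edges: list[DirectedSeedEdge],
    consensus_edges: dict[tuple[str, str], float],
    coexpr_edges: pd.DataFrame,
    tfs: set[str] | None = None,
) -> RegulatoryNetwork:
    """Final mixed module network.

    Directed edges: prior/motif seeds, plus consensus edges whose endpoint
    pair is also a co-expression link.  Co-expression links not covered by a
    directed edge stay undirected.
    """
    tfs = tfs or set()
    net = RegulatoryNetwork()
    links = {tuple(sorted((a, b))) for a, b in
             zip(coexpr_edges["gene_a"], coexpr_edges["gene_b"])}
    for e in seed_edges:
        net.add_node(e.tf, "tf" if e.tf in tfs else "gene")
        net.add_node(e.target, "tf" if e.target in tfs else "gene")
        net.add_edge(Edge(e.tf, e.target, True, (e.provenance,), 1.0))
    for (u, v), conf in sorted(consensus_edges.items()):
        if tuple(sorted((u, v))) in links:
            net.add_node(u, "tf" if u in tfs else "gene")
            net.add_node(v, "tf" if v in tfs else "gene")
            net.add_edge(Edge(u, v, True, ("bayesian",), conf))
    covered = {tuple(sorted((e.source, e.target))) for e in net.directed_edges()}
    for a, b in sorted(links):
        if (a, b) not in covered:
            net.add_node(a, "tf" if a in tfs else "gene")
            net.add_node(b, "tf" if b in tfs else "gene")
            net.add_edge(Edge(a, b, False, ("coexpression",), 1.0))
    return net
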