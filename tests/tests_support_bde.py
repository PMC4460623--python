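"""Shared independent oracle for BDe scores: sequential-prediction marginal
likelihood with Dirichlet counts, plus the 25-DAG enumeration on 3 nodes."""

import itertools

import numpy as np


def prequential_family(node, parents, data, ess, arity):
    q = arity ** len(parents)
    a_ijk = ess / (q * arity)
    counts: dict = {}
    log_ml = 0.0
    for s in range(data.shape[1]):
        j = 0
        for p in parents:
            j = j * arity + int(data.loc[p].iloc[s])
        k = int(data.loc[node].iloc[s])
        n_jk = counts.get((j, k), 0)
        n_j = sum(counts.get((j, kk), 0) for kk in range(arity))
        log_ml += np.log((a_ijk + n_jk) / (ess / q + n_j))
        counts[(j, k)] = n_jk + 1
    return log_ml


def prequential_total(edges, data, ess, arity):
    parents = {n: tuple(sorted(u for u, v in edges if v == n)) for n in data.index}
    return sum(
        prequential_family(n, parents[n], data, ess, arity) for n in data.index
    )


def all_dags_3_nodes(nodes=("a", "b", "c")):
    pairs = list(itertools.permutations(nodes, 2))
    dags = []
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = {p for p, m in zip(pairs, mask) if m}
        if any((v, u) in edges for u, v in edges):
            continue
        if any(
            (x, y) in edges and (y, z) in edges and (z, x) in edges
            for x, y, z in itertools.permutations(nodes, 3)
        ):
            continue
        dags.append(edges)
    return dags
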