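import itertools

import numpy as np
import pandas as pd
import pytest

from drivernet import bayesnet
from drivernet.motifs import DirectedSeedEdge


def prequential_family_score(node, parents, data, ess, arity):
    """Independent oracle: log marginal likelihood by sequential prediction
    with Dirichlet counts updated one observation at a time."""
    q = arity ** len(parents)
    a_ijk = ess / (q * arity)
    counts = {}
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


def all_dags_3_nodes():
    """All 25 DAGs on three labeled nodes."""
    nodes = ["a", "b", "c"]
    pairs = list(itertools.permutations(nodes, 2))
    dags = []
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = {p for p, m in zip(pairs, mask) if m}
        # reject graphs with 2-cycles or 3-cycles
        if any((v, u) in edges for u, v in edges):
            continue
        if any(
            (a, b) in edges and (b, c) in edges and (c, a) in edges
            for a, b, c in itertools.permutations(nodes, 3)
        ):
            continue
        dags.append(edges)
    assert len(dags) == 25
    return dags


class TestDiscretize:
    def test_equal_frequency_bins(self):
        expr = pd.DataFrame([np.arange(1.0, 10.0)], index=["g"])
        out = bayesnet.discretize(expr, r=3)
        assert out.loc["g"].tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_constant_gene_all_zero(self):
        expr = pd.DataFrame([[5.0] * 6], index=["g"])
        with pytest.warns(UserWarning, match="constant"):
            out = bayesnet.discretize(expr, r=3)
        assert (out.loc["g"] == 0).all()

    def test_ties_deterministic_across_runs(self):
        expr = pd.DataFrame([[1.0, 2.0, 2.0, 2.0, 3.0, 4.0]], index=["g"])
        a = bayesnet.discretize(expr, r=3)
        b = bayesnet.discretize(expr.copy(), r=3)
        pd.testing.assert_frame_equal(a, b)

    def test_arity_below_two_rejected(self):
        with pytest.raises(ValueError):
            bayesnet.discretize(pd.DataFrame([[1.0, 2.0]]), r=1)


class TestBdeScore:
    def test_worked_binary_example(self):
        data = pd.DataFrame([[1, 1, 1, 0]], index=["x"])
        score = bayesnet.bde_family_score("x", (), data, ess=1.0, arity=2)
        assert score == pytest.approx(np.log(5 / 128), abs=1e-12)

    def test_zero_rows_score_zero(self):
        data = pd.DataFrame(np.empty((2, 0), dtype=int), index=["x", "y"])
        assert bayesnet.bde_family_score("x", ("y",), data, 1.0, 2) == 0.0

    def test_total_decomposes_into_families(self, rng):
        data = pd.DataFrame(rng.integers(0, 2, size=(3, 30)),
                            index=["a", "b", "c"])
        edges = {("a", "b"), ("a", "c")}
        total = bayesnet.bde_total_score(edges, data, 1.0, 2)
        manual = (
            bayesnet.bde_family_score("a", (), data, 1.0, 2)
            + bayesnet.bde_family_score("b", ("a",), data, 1.0, 2)
            + bayesnet.bde_family_score("c", ("a",), data, 1.0, 2)
        )
        assert total == pytest.approx(manual, abs=1e-12)

    @pytest.mark.parametrize("parents", [(), ("p1",), ("p1", "p2")])
    def test_matches_prequential_oracle(self, parents, rng):
        nodes = ["x", "p1", "p2"]
        data = pd.DataFrame(rng.integers(0, 3, size=(3, 40)), index=nodes)
        score = bayesnet.bde_family_score("x", parents, data, ess=2.0, arity=3)
        oracle = prequential_family_score("x", parents, data, ess=2.0, arity=3)
        assert score == pytest.approx(oracle, abs=1e-9)

    def test_all_25_dags_match_oracle(self, rng):
        data = pd.DataFrame(rng.integers(0, 2, size=(3, 25)),
                            index=["a", "b", "c"])
        for edges in all_dags_3_nodes():
            total = bayesnet.bde_total_score(edges, data, 1.0, 2)
            parents = {n: tuple(sorted(u for u, v in edges if v == n))
                       for n in ["a", "b", "c"]}
            oracle = sum(
                prequential_family_score(n, parents[n], data, 1.0, 2)
                for n in ["a", "b", "c"]
            )
            assert total == pytest.approx(oracle, abs=1e-9)

    def test_invalid_ess_rejected(self):
        with pytest.raises(ValueError):
            bayesnet.BDeParams(ess=0.0)


class TestSparseCandidates:
    def test_copy_of_variable_always_selected(self, rng):
        x = rng.integers(0, 3, size=200)
        data = pd.DataFrame(
            [x, x.copy(), rng.integers(0, 3, size=200), rng.integers(0, 3, size=200)],
            index=["x", "xcopy", "n1", "n2"],
        )
        cands = bayesnet.sparse_candidates(data, k=1)
        assert cands["x"] == {"xcopy"}
        assert cands["xcopy"] == {"x"}

    def test_independent_noise_has_near_zero_mi(self, rng):
        x = rng.integers(0, 4, size=10_000)
        y = rng.integers(0, 4, size=10_000)
        assert bayesnet.mutual_information(x, y) <= 0.01

    def test_k_equals_n_minus_one_selects_all(self, rng):
        data = pd.DataFrame(rng.integers(0, 2, size=(4, 30)),
                            index=["a", "b", "c", "d"])
        cands = bayesnet.sparse_candidates(data, k=3)
        for node, cs in cands.items():
            assert cs == set(data.index) - {node}

    def test_seed_parents_always_included(self, rng):
        data = pd.DataFrame(rng.integers(0, 2, size=(4, 30)),
                            index=["a", "b", "c", "d"])
        cands = bayesnet.sparse_candidates(data, k=1, seed_edges={("d", "a")})
        assert "d" in cands["a"]


class TestLearnStructure:
    def _pair_data(self, rng, n=300):
        a = rng.integers(0, 2, size=n)
        flip = rng.random(n) < 0.05
        b = np.where(flip, 1 - a, a)
        return pd.DataFrame([a, b], index=["A", "B"])

    def test_strong_dependence_learned_one_direction(self, rng):
        data = self._pair_data(rng)
        cands = {"A": {"B"}, "B": {"A"}}
        dag = bayesnet.learn_structure(data, set(), cands, run_seed=0, arity=2)
        assert dag.edges in ({("A", "B")}, {("B", "A")})

    def test_local_optimum_returns_seed_unchanged(self, rng):
        # independent nodes: empty graph is already optimal
        data = pd.DataFrame(rng.integers(0, 2, size=(2, 400)), index=["A", "B"])
        cands = {"A": {"B"}, "B": {"A"}}
        dag = bayesnet.learn_structure(data, set(), cands, run_seed=0, arity=2)
        assert dag.edges == set()

    def test_score_never_decreases(self, rng):
        data = pd.DataFrame(rng.integers(0, 3, size=(5, 100)),
                            index=list("abcde"))
        cands = bayesnet.sparse_candidates(data, k=3)
        dag = bayesnet.learn_structure(data, set(), cands, run_seed=1, arity=3)
        assert all(np.diff(dag.score_trace) >= -1e-9)

    def test_result_is_acyclic(self, synth):
        import networkx as nx

        t = synth.truth
        label = 1
        genes = sorted(g for g, m in t.module_assignment.items() if m == label)
        data = bayesnet.discretize(synth.cohort.expression.loc[genes], 3)
        seed_pairs = set(t.true_dag_per_module[label][:10])
        cands = bayesnet.sparse_candidates(data, 5, seed_pairs)
        dag = bayesnet.learn_structure(data, seed_pairs, cands, run_seed=0, arity=3)
        g = nx.DiGraph(list(dag.edges))
        assert nx.is_directed_acyclic_graph(g)

    def test_cyclic_seed_broken(self, rng):
        data = pd.DataFrame(rng.integers(0, 2, size=(2, 50)), index=["A", "B"])
        cands = {"A": {"B"}, "B": {"A"}}
        dag = bayesnet.learn_structure(
            data, {("A", "B"), ("B", "A")}, cands, run_seed=0, arity=2
        )
        assert len(dag.edges) <= 1


class TestConsensus:
    def _dag(self, edges, nodes=("a", "b", "c")):
        return bayesnet.LearnedDag(nodes=list(nodes), edges=set(edges),
                                   score=0.0, run_seed=0)

    def test_edge_in_two_runs_kept(self):
        dags = [self._dag({("a", "b")}), self._dag({("a", "b")}), self._dag(set())]
        cons = bayesnet.consensus(dags)
        assert cons == {("a", "b"): pytest.approx(2 / 3)}

    def test_edge_in_one_run_dropped(self):
        dags = [self._dag(set()), self._dag(set()), self._dag({("a", "b")})]
        assert bayesnet.consensus(dags) == {}

    def test_edge_in_all_runs_full_confidence(self):
        dags = [self._dag({("a", "b")})] * 3
        assert bayesnet.consensus(dags)[("a", "b")] == 1.0

    def test_node_set_mismatch_errors(self):
        with pytest.raises(ValueError, match="node sets"):
            bayesnet.consensus([self._dag(set()), self._dag(set(), nodes=("x",))])


class TestAssembleGrn:
    def _coexpr(self, *pairs):
        return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    def test_consensus_edge_confirmed_by_coexpression(self):
        net = bayesnet.assemble_grn([], {("A", "B"): 1.0}, self._coexpr(("A", "B")))
        directed = net.directed_edges()
        assert len(directed) == 1
        assert (directed[0].source, directed[0].target) == ("A", "B")
        assert directed[0].provenance == ("bayesian",)

    def test_consensus_edge_without_link_excluded(self):
        net = bayesnet.assemble_grn([], {("A", "B"): 1.0}, self._coexpr(("A", "C")))
        assert all(
            (e.source, e.target) != ("A", "B") for e in net.directed_edges()
        )

    def test_unconfirmed_link_stays_undirected(self):
        net = bayesnet.assemble_grn([], {}, self._coexpr(("A", "B")))
        assert len(net.undirected_edges()) == 1
        assert net.undirected_edges()[0].provenance == ("coexpression",)

    def test_seed_edges_always_directed(self):
        seeds = [DirectedSeedEdge("A", "B", "curated")]
        net = bayesnet.assemble_grn(seeds, {}, self._coexpr(("A", "B")))
        assert len(net.directed_edges()) == 1
        assert len(net.undirected_edges()) == 0


class TestStructureRecovery:
    def test_consensus_f1_on_known_dag(self):
        nodes = [f"n{i}" for i in range(8)]
        true = {("n0", "n1"), ("n0", "n2"), ("n1", "n3"), ("n2", "n4"),
                ("n3", "n5"), ("n4", "n6"), ("n1", "n7")}
        f1s = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = {}
            parents = {v: [u for u, w in true if w == v] for v in nodes}
            for v in nodes:
                if parents[v]:
                    base = 0.9 * np.mean([x[p] for p in parents[v]], axis=0)
                    x[v] = base + np.sqrt(1 - 0.81) * rng.normal(size=500)
                else:
                    x[v] = rng.normal(size=500)
            expr = pd.DataFrame(np.vstack([x[v] for v in nodes]), index=nodes)
            data = bayesnet.discretize(expr, 3)
            cands = bayesnet.sparse_candidates(data, 4)
            cons, _ = bayesnet.learn_consensus(data, set(), cands, base_seed=seed)
            skel_true = {frozenset(e) for e in true}
            skel_got = {frozenset(e) for e in cons}
            tp = len(skel_true & skel_got)
            prec = tp / max(len(skel_got), 1)
            rec = tp / len(skel_true)
            f1s.append(2 * prec * rec / max(prec + rec, 1e-9))
        assert np.mean(f1s) >= 0.6
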