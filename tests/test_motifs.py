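import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from drivernet import motifs


def enumerate_distribution(pwm: motifs.PWM) -> dict[int, float]:
    """Exhaustive null distribution over all 4^L sequences."""
    out: Counter = Counter()
    for word in itertools.product(range(4), repeat=pwm.length):
        score = int(sum(pwm.int_scores[b, j] for j, b in enumerate(word)))
        prob = 1.0
        for b in word:
            prob *= pwm.background[b]
        out[score] += prob
    return dict(out)


class TestScoreDistribution:
    @pytest.mark.parametrize("L", [1, 2, 4, 6])
    def test_dp_equals_enumeration(self, L, rng):
        counts = rng.integers(0, 30, size=(4, L)).astype(float)
        pwm = motifs.pwm_from_counts(f"M{L}", counts)
        dp = pwm.score_distribution()
        enum = enumerate_distribution(pwm)
        assert set(dp) == set(enum)
        for s in dp:
            assert dp[s] == pytest.approx(enum[s], abs=1e-12)

    def test_single_base_pwm_max_score_quarter(self):
        pwm = motifs.pwm_from_counts("A1", np.array([[1.0], [0], [0], [0]]))
        max_score = max(pwm.score_distribution())
        assert pwm.score_pvalue(max_score) == pytest.approx(0.25)

    def test_distribution_sums_to_one(self, rng):
        pwm = motifs.pwm_from_counts("M", rng.integers(0, 9, size=(4, 5)).astype(float))
        assert sum(pwm.score_distribution().values()) == pytest.approx(1.0)

    def test_threshold_tail_never_exceeds_p(self, rng):
        pwm = motifs.pwm_from_counts("M", rng.integers(0, 30, size=(4, 4)).astype(float))
        for p in (0.5, 0.1, 1e-2, 1e-3):
            thr = pwm.threshold_for_pvalue(p)
            assert pwm.score_pvalue(thr) <= p


class TestScanning:
    def test_reverse_complement_invariance(self, rng):
        pwm = motifs.pwm_from_counts("M", rng.integers(0, 30, size=(4, 6)).astype(float))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert motifs.best_hit_score(seq, pwm) == motifs.best_hit_score(
            motifs.reverse_complement(seq), pwm
        )

    def test_planted_site_found_on_either_strand(self):
        counts = np.full((4, 6), 0.0)
        consensus = "ACGTAC"
        for j, c in enumerate(consensus):
            counts["ACGT".index(c), j] = 100.0
        pwm = motifs.pwm_from_counts("M", counts)
        thr = pwm.threshold_for_pvalue(1e-3)
        background = "T" * 40
        fwd = background + consensus + background
        rev = background + motifs.reverse_complement(consensus) + background
        assert motifs.best_hit_score(fwd, pwm) >= thr
        assert motifs.best_hit_score(rev, pwm) >= thr

    def test_windows_with_non_acgt_skipped(self):
        pwm = motifs.pwm_from_counts("M", np.full((4, 3), 5.0))
        assert motifs.best_hit_score("NNN", pwm) is None


class TestPwmScan:
    def _setup(self):
        counts = np.full((4, 6), 0.0)
        for j, c in enumerate("ACGTAC"):
            counts["ACGT".index(c), j] = 100.0
        pwm = motifs.pwm_from_counts("MOTIF1", counts)
        promoters = {
            "hit": "T" * 30 + "ACGTAC" + "T" * 30,
            "miss": "T" * 66,
            "revhit": "T" * 30 + motifs.reverse_complement("ACGTAC") + "T" * 30,
        }
        return pwm, promoters

    def test_hit_and_miss(self):
        pwm, promoters = self._setup()
        edges = motifs.pwm_scan(promoters, [pwm], {"MOTIF1": "TF1"},
                                ["hit", "miss"], {"TF1"}, p_threshold=1e-3)
        assert {(e.tf, e.target) for e in edges} == {("TF1", "hit")}

    def test_opposite_strand_hits_deduplicated(self):
        pwm, promoters = self._setup()
        both = {"g": promoters["hit"] + promoters["revhit"]}
        edges = motifs.pwm_scan(both, [pwm], {"MOTIF1": "TF1"},
                                ["g"], {"TF1"}, p_threshold=1e-3)
        assert len(edges) == 1

    def test_high_non_acgt_promoter_skipped(self):
        pwm, _ = self._setup()
        with pytest.warns(UserWarning, match="non-ACGT"):
            edges = motifs.pwm_scan({"g": "N" * 50 + "ACGTAC"}, [pwm],
                                    {"MOTIF1": "TF1"}, ["g"], {"TF1"}, 1e-3)
        assert edges == []


class TestMarkTfs:
    def test_union_of_tables(self):
        tfs = motifs.mark_tfs(["a", "b", "c"], [["a"], ["b", "z"]])
        assert tfs == {"a", "b"}

    def test_gene_in_no_table(self):
        assert motifs.mark_tfs(["a"], [["x"], ["y"]]) == set()

    def test_gene_in_all_tables_counted_once(self):
        assert motifs.mark_tfs(["a"], [["a"], ["a"], ["a"]]) == {"a"}

    def test_no_tables_errors(self):
        with pytest.raises(ValueError):
            motifs.mark_tfs(["a"], [])


class TestCuratedEdges:
    def _links(self, *pairs):
        return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    def test_prior_directs_coexpression_link(self):
        priors = pd.DataFrame([{"tf": "A", "target": "B"}])
        edges = motifs.curated_edges(self._links(("A", "B")), [priors], {"A"})
        assert [(e.tf, e.target) for e in edges] == [("A", "B")]

    def test_prior_without_link_ignored(self):
        priors = pd.DataFrame([{"tf": "A", "target": "B"}])
        edges = motifs.curated_edges(self._links(("A", "C")), [priors], {"A"})
        assert edges == []

    def test_bidirectional_priors_give_two_edges(self):
        priors = pd.DataFrame([{"tf": "A", "target": "B"}, {"tf": "B", "target": "A"}])
        edges = motifs.curated_edges(self._links(("A", "B")), [priors], {"A", "B"})
        assert {(e.tf, e.target) for e in edges} == {("A", "B"), ("B", "A")}

    def test_output_subset_of_link_endpoints(self, rng):
        genes = [f"g{i}" for i in range(10)]
        links = self._links(*[
            tuple(rng.choice(genes, 2, replace=False)) for _ in range(15)
        ])
        priors = pd.DataFrame(
            [{"tf": a, "target": b}
             for a, b in zip(rng.choice(genes, 20), rng.choice(genes, 20))]
        )
        edges = motifs.curated_edges(links, [priors], set(genes))
        link_pairs = {frozenset(p) for p in zip(links["gene_a"], links["gene_b"])}
        assert all(frozenset((e.tf, e.target)) in link_pairs for e in edges)


class TestJasparIO:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(1, 50, size=(4, 7)).astype(float)
        pwm = motifs.pwm_from_counts("MA0001.1", counts)
        path = tmp_path / "m.jaspar"
        motifs.write_jaspar([pwm], path)
        back = motifs.read_jaspar(path)
        assert len(back) == 1
        assert back[0].motif_id == "MA0001.1"
        assert back[0].length == 7
        # probabilities survive the integer-scaled round trip approximately
        assert np.allclose(back[0].probs, pwm.probs, atol=0.02)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"g1": "ACGTACGT" * 20, "g2": "TTTT"}
        path = tmp_path / "p.fa"
        motifs.write_fasta(seqs, path)
        assert motifs.read_fasta(path) == seqs
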