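import numpy as np
import pytest
from scipy.stats import kstest

from drivernet import proximity as prox
from drivernet.io_preprocess import GenomicFeature, SomaticVariant


def _feat(chrom, start, end, fid):
    return GenomicFeature(chrom, start, end, "+", fid, "mirna_locus")


def _var(chrom, pos, ref="C", alt="T", sample="s"):
    return SomaticVariant(chrom, pos, ref, alt, sample)


class TestDistance:
    def test_upstream(self):
        assert prox.variant_feature_distance(_var("c", 100), _feat("c", 200, 300, "f")) == 100

    def test_inside_is_zero(self):
        assert prox.variant_feature_distance(_var("c", 250), _feat("c", 200, 300, "f")) == 0

    def test_downstream_counts_from_last_base(self):
        assert prox.variant_feature_distance(_var("c", 305), _feat("c", 200, 300, "f")) == 6


class TestFindProximal:
    def test_within_window(self):
        cases = prox.find_proximal(
            [_feat("chr1", 740_000, 740_080, "mir")], [_var("chr1", 500_000)], 250_000
        )
        assert len(cases) == 1
        assert cases[0].distance == 240_000

    def test_beyond_window_excluded(self):
        cases = prox.find_proximal(
            [_feat("chr1", 760_001, 760_081, "mir")], [_var("chr1", 500_000)], 250_000
        )
        assert cases == []

    def test_genotype_filter_excludes_non_c_ref(self):
        feats = [_feat("chr1", 1_000, 1_001, "cpg")]
        variants = [_var("chr1", 1_500, "T", "A"), _var("chr1", 1_600, "C", "A")]
        cases = prox.find_proximal(feats, variants, 3_000, prox.CPG_GENOTYPES)
        assert len(cases) == 1
        assert cases[0].variant.ref == "C"

    def test_different_chromosome_never_matches(self):
        cases = prox.find_proximal(
            [_feat("chr2", 100, 200, "f")], [_var("chr1", 100)], 10_000
        )
        assert cases == []

    def test_matches_allpairs_bruteforce(self, rng):
        feats = [
            _feat(f"chr{rng.integers(1, 4)}", int(p), int(p) + 80, f"f{i}")
            for i, p in enumerate(rng.integers(0, 900_000, 120))
        ]
        variants = [
            _var(f"chr{rng.integers(1, 4)}", int(p))
            for p in rng.integers(0, 1_000_000, 80)
        ]
        window = 50_000
        cases = prox.find_proximal(feats, variants, window)
        expected = set()
        for v in variants:
            for f in feats:
                if v.chrom == f.chrom and prox.variant_feature_distance(v, f) <= window:
                    expected.add((v.chrom, v.pos, f.feature_id))
        got = {(c.variant.chrom, c.variant.pos, c.feature.feature_id) for c in cases}
        assert got == expected


class TestPermutationTest:
    SIZES = {"chr1": 2_000_000}

    def _null_instance(self, rs, n_feats=20, n_vars=30):
        feats = [
            _feat("chr1", int(p), int(p) + 80, f"f{i}")
            for i, p in enumerate(np.sort(rs.integers(0, 1_900_000, n_feats)))
        ]
        variants = [_var("chr1", int(p)) for p in rs.integers(0, 2_000_000, n_vars)]
        return feats, variants

    def test_probability_floor(self):
        # feature right on top of the variant: nothing ranks closer
        feats = [_feat("chr1", 1_000_000, 1_000_080, "f")]
        variants = [_var("chr1", 1_000_010)]
        cases = prox.find_proximal(feats, variants, 250_000)
        res = prox.permutation_test(cases, variants, self.SIZES, n_perm=1000,
                                    seed=0, compute_iteration_pvalues=False)
        assert res.empirical_p >= 1 / 1001
        assert res.empirical_p <= 0.05

    def test_no_cases_errors(self):
        with pytest.raises(ValueError, match="no observed cases"):
            prox.permutation_test([], [], self.SIZES)

    def test_unknown_chromosome_errors(self):
        feats = [_feat("chr1", 100, 180, "f")]
        variants = [_var("chrZ", 50)]
        cases = [prox.ProximityCase(variants[0], feats[0], 10)]
        with pytest.raises(ValueError, match="chrZ"):
            prox.permutation_test(cases, variants, self.SIZES)

    def test_null_pvalues_uniform(self):
        ps = []
        for rep in range(150):
            rs = np.random.default_rng(rep)
            feats, variants = self._null_instance(rs)
            cases = prox.find_proximal(feats, variants, 250_000)
            if not cases:
                continue
            res = prox.permutation_test(cases, variants, self.SIZES, n_perm=99,
                                        seed=10_000 + rep,
                                        compute_iteration_pvalues=False)
            ps.append(res.empirical_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_proximity_significant(self, synth):
        c, t = synth.cohort, synth.truth
        de_loci = [f for f in synth.mirna_loci if f.feature_id in t.de_mirnas]
        cases = prox.find_proximal(de_loci, c.variants, 250_000)
        res = prox.permutation_test(cases, c.variants, synth.chrom_sizes,
                                    n_perm=999, seed=7,
                                    compute_iteration_pvalues=False)
        assert res.empirical_p <= 0.01

    def test_iteration_pvalues_exported(self):
        rs = np.random.default_rng(0)
        feats, variants = self._null_instance(rs)
        cases = prox.find_proximal(feats, variants, 250_000)
        res = prox.permutation_test(cases, variants, self.SIZES, n_perm=20, seed=1)
        assert res.iteration_pvalues is not None
        assert len(res.iteration_pvalues) == 20
        assert ((res.iteration_pvalues >= 0) & (res.iteration_pvalues <= 1)).all()


class TestSplitByDirection:
    def _cases(self, specs):
        out = []
        for gene, ref, alt in specs:
            f = GenomicFeature("chr1", 100, 101, ".", f"cpg_{gene}", "cpg_site")
            out.append(prox.ProximityCase(_var("chr1", 150, ref, alt), f, 50))
        return out

    def test_counts_by_direction_and_genotype(self):
        cases = self._cases([("a", "C", "T"), ("b", "C", "T"), ("c", "C", "G")])
        table = prox.split_by_methylation_direction(
            cases, {"a": "up", "b": "up", "c": "down"},
            {"cpg_a": "a", "cpg_b": "b", "cpg_c": "c"},
        )
        assert table.loc["up", "C->T"] == 2
        assert table.loc["down", "C->G"] == 1

    def test_all_up_gives_zero_down_row(self):
        cases = self._cases([("a", "C", "T")])
        table = prox.split_by_methylation_direction(cases, {"a": "up"}, {"cpg_a": "a"})
        assert table.loc["down"].sum() == 0

    def test_genotype_columns_sum_to_total(self, synth):
        c, t = synth.cohort, synth.truth
        dm_cpgs = [f for f in synth.cpgs
                   if f.feature_id.startswith("cpg_G") and f.feature_id[4:] in t.dm_genes]
        cases = prox.find_proximal(dm_cpgs, c.variants, 3_000, prox.CPG_GENOTYPES)
        mapping = {f.feature_id: f.feature_id[4:] for f in dm_cpgs}
        table = prox.split_by_methylation_direction(cases, t.dm_genes, mapping)
        assert table.to_numpy().sum() == len(cases)

    def test_unmapped_feature_excluded(self):
        cases = self._cases([("a", "C", "T")])
        table = prox.split_by_methylation_direction(cases, {}, {})
        assert table.to_numpy().sum() == 0


class TestExclusivity:
    def test_background_neighbor_blocks_exclusivity(self):
        dys = _feat("chr1", 1_000, 1_080, "dys")
        bg = _feat("chr1", 2_000, 2_080, "bg")
        v = _var("chr1", 1_500)
        cases = [prox.ProximityCase(v, dys, 420)]
        out = prox.exclusivity_check(cases, [dys, bg], {"dys"}, 250_000)
        assert not out.iloc[0]["exclusive"]

    def test_only_dysregulated_neighbors_is_exclusive(self):
        dys = _feat("chr1", 1_000, 1_080, "dys")
        v = _var("chr1", 1_500)
        cases = [prox.ProximityCase(v, dys, 420)]
        out = prox.exclusivity_check(cases, [dys], {"dys"}, 250_000)
        assert out.iloc[0]["exclusive"]

    def test_empty_background_catalogue_all_exclusive(self):
        dys = [_feat("chr1", p, p + 80, f"d{p}") for p in (1_000, 5_000)]
        variants = [_var("chr1", 1_200), _var("chr1", 5_100)]
        cases = prox.find_proximal(dys, variants, 250_000)
        out = prox.exclusivity_check(cases, dys, {f.feature_id for f in dys}, 250_000)
        assert out["exclusive"].all()
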