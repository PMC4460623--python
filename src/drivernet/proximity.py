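"""Genomic proximity of somatic variants to regulatory features, with a
chromosome-preserving permutation test.

Distance from a variant to an interval feature is the distance to its
nearest base (0 when the variant falls inside).  Significance: each
iteration redraws the per-chromosome variant positions uniformly, recomputes
the nearest-variant distance for every observed-case feature, and compares
observed vs permuted distances by a one-sided Wilcoxon rank-sum; the
empirical p is (1 + b)/(1 + n_perm) with b the number of iterations whose
permuted distances rank at least as close as the observed ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .io_preprocess import GenomicFeature, SomaticVariant

logger = logging.getLogger(__name__)

#: Default genotype filter of the CpG analysis: C-reference transversions
#: and the deamination transition.
CPG_GENOTYPES = (("C", "A"), ("C", "G"), ("C", "T"))


@dataclass(frozen=True)
class ProximityCase:
    variant: SomaticVariant
    feature: GenomicFeature
    distance: int


def variant_feature_distance(variant: SomaticVariant, feature: GenomicFeature) -> int:
    """bp distance to the nearest base of the feature (0 if inside)."""
    if variant.pos < feature.start:
        return feature.start - variant.pos
    if variant.pos >= feature.end:
        return variant.pos - feature.end + 1
    return 0


def find_proximal(
    features: Sequence[GenomicFeature],
    variants: Sequence[SomaticVariant],
    window_bp: int,
    genotype_filter: Sequence[tuple[str, str]] | None = None,
) -> list[ProximityCase]:
    """All (variant, feature) pairs on the same chromosome within the window.

    ``genotype_filter`` restricts variants to the listed (ref, alt) pairs;
    None/empty keeps every variant.  Output is sorted and deduplicated.
    """
    if genotype_filter:
        allowed = set(genotype_filter)
        variants = [v for v in variants if (v.ref, v.alt) in allowed]
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    seen: set[tuple[str, int, str, str, str]] = set()
    cases: list[ProximityCase] = []
    for v in variants:
        for f in by_chrom.get(v.chrom, ()):
            d = variant_feature_distance(v, f)
            if d <= window_bp:
                key = (v.chrom, v.pos, v.ref, v.alt, f.feature_id)
                if key not in seen:
                    seen.add(key)
                    cases.append(ProximityCase(v, f, d))
    cases.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.feature.feature_id))
    logger.info("find_proximal: %d case(s) within %d bp", len(cases), window_bp)
    return cases


@dataclass
class PermutationResult:
    n_perm: int
    observed_distances: np.ndarray
    empirical_p: float
    b: int
    iteration_pvalues: np.ndarray = field(repr=False, default=None)


def _nearest_distances(
    feature_pos: np.ndarray,
    feature_chrom: np.ndarray,
    positions_by_chrom: Mapping[str, np.ndarray],
) -> np.ndarray:
    out = np.empty(feature_pos.shape[0], dtype=float)
    for i, (chrom, span) in enumerate(zip(feature_chrom, feature_pos)):
        pos = positions_by_chrom.get(chrom)
        if pos is None or pos.size == 0:
            out[i] = np.inf
            continue
        start, end = span
        left = pos < start
        inside = (pos >= start) & (pos < end)
        if inside.any():
            out[i] = 0.0
        else:
            d = np.where(left, start - pos, pos - end + 1)
            out[i] = d.min()
    return out


def permutation_test(
    observed_cases: Sequence[ProximityCase],
    variants: Sequence[SomaticVariant],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    compute_iteration_pvalues: bool = True,
) -> PermutationResult:
    """Chromosome-preserving position-permutation significance test.

    ``compute_iteration_pvalues`` additionally exports the per-iteration
    one-sided Wilcoxon p-values (slower; the empirical p needs only ranks).
    """
    if not observed_cases:
        raise ValueError("permutation_test: no observed cases")
    for v in variants:
        if v.chrom not in chrom_sizes:
            raise ValueError(f"variant chromosome {v.chrom} not in size table")
    # one distance per unique case feature: min over its cases, which equals
    # the distance to the nearest observed variant (comparable with the
    # nearest-permuted-variant distances computed below)
    per_feature: dict[str, ProximityCase] = {}
    for c in observed_cases:
        prev = per_feature.get(c.feature.feature_id)
        if prev is None or c.distance < prev.distance:
            per_feature[c.feature.feature_id] = c
    uniq = [per_feature[fid] for fid in sorted(per_feature)]
    obs = np.array([c.distance for c in uniq], dtype=float)
    feat_span = np.array([[c.feature.start, c.feature.end] for c in uniq])
    feat_chrom = np.array([c.feature.chrom for c in uniq])
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.chrom] = counts.get(v.chrom, 0) + 1
    rng = np.random.default_rng(seed)
    m = obs.size
    b = 0
    iter_p = np.empty(n_perm)
    for it in range(n_perm):
        permuted = {
            chrom: rng.integers(0, chrom_sizes[chrom], size=cnt)
            for chrom, cnt in counts.items()
        }
        assert all(permuted[c].size == counts[c] for c in counts)
        perm_d = _nearest_distances(feat_span, feat_chrom, permuted)
        # rank-sum of the permuted sample within the pooled distances
        ranks = rankdata(np.concatenate([obs, perm_d]))
        if ranks[m:].sum() <= ranks[:m].sum():
            b += 1
        if compute_iteration_pvalues:
            clean = np.where(np.isfinite(perm_d), perm_d, 4e9)
            iter_p[it] = mannwhitneyu(obs, clean, alternative="less").pvalue
    if not compute_iteration_pvalues:
        iter_p = None
    p = (1 + b) / (1 + n_perm)
    logger.info("permutation_test: empirical p = %.4g (b = %d / %d)", p, b, n_perm)
    return PermutationResult(
        n_perm=n_perm, observed_distances=obs, empirical_p=p, b=b,
        iteration_pvalues=iter_p,
    )


def split_by_methylation_direction(
    cases: Sequence[ProximityCase],
    dm_direction: Mapping[str, str],
    feature_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Contingency counts {up, down} methylation x (ref->alt) genotype.

    ``dm_direction`` maps differentially methylated gene -> 'up'/'down';
    ``feature_gene`` maps feature id -> gene (identity when omitted).
    Unmapped features are excluded and logged.
    """
    genotypes = sorted({f"{c.variant.ref}->{c.variant.alt}" for c in cases})
    table = pd.DataFrame(0, index=["up", "down"], columns=genotypes, dtype=int)
    dropped = 0
    for c in cases:
        gene = (feature_gene or {}).get(c.feature.feature_id, c.feature.feature_id)
        direction = dm_direction.get(gene)
        if direction not in ("up", "down"):
            dropped += 1
            continue
        table.loc[direction, f"{c.variant.ref}->{c.variant.alt}"] += 1
    if dropped:
        logger.info("split_by_methylation_direction: %d unmapped case(s) excluded", dropped)
    return table


def exclusivity_check(
    cases: Sequence[ProximityCase],
    all_features: Sequence[GenomicFeature],
    dysregulated_ids: set[str],
    window_bp: int,
) -> pd.DataFrame:
    """Flag case variants proximal ONLY to dysregulated features.

    A variant is exclusive iff no non-dysregulated feature from the full
    catalogue lies within the window.
    """
    background = [f for f in all_features if f.feature_id not in dysregulated_ids]
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in background:
        by_chrom.setdefault(f.chrom, []).append(f)
    rows = []
    seen: set[tuple[str, int, str, str]] = set()
    for c in cases:
        v = c.variant
        vkey = (v.chrom, v.pos, v.ref, v.alt)
        if vkey in seen:
            continue
        seen.add(vkey)
        n_bg = sum(
            1 for f in by_chrom.get(v.chrom, ())
            if variant_feature_distance(v, f) <= window_bp
        )
        rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "n_background_neighbors": n_bg, "exclusive": n_bg == 0})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "n_background_neighbors", "exclusive"])


def cases_to_frame(cases: Sequence[ProximityCase]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.variant.chrom, "pos": c.variant.pos,
            "ref": c.variant.ref, "alt": c.variant.alt,
            "sample_id": c.variant.sample_id,
            "feature_id": c.feature.feature_id,
            "feature_class": c.feature.feature_class,
            "distance": c.distance,
        }
        for c in cases
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id",
                                       "feature_id", "feature_class", "distance"])
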