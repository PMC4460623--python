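"""Three-method differential calling with a 2-of-3 majority vote.

Methods: a permutation-based SAM-style statistic d = dm/(s + s0), an
empirical-Bayes moderated t with method-of-moments variance prior, and the
rank-based AUC-ROC.  A feature is called differential when at least two
methods flag it; direction is the sign of (mean tumor - mean normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class SamParams:
    s0: float | None = None  # None -> percentile of per-feature s
    s0_percentile: float = 50.0
    n_perm: int = 100
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be non-negative")


@dataclass
class ModTParams:
    """Fitted variance-prior hyperparameters (d0 may be inf)."""

    d0: float
    s0_sq: float


def _group_stats(x_tumor: np.ndarray, x_normal: np.ndarray):
    x_tumor = np.atleast_2d(np.asarray(x_tumor, dtype=float))
    x_normal = np.atleast_2d(np.asarray(x_normal, dtype=float))
    n1, n2 = x_tumor.shape[1], x_normal.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    dm = x_tumor.mean(axis=1) - x_normal.mean(axis=1)
    ss = x_tumor.var(axis=1, ddof=1) * (n1 - 1) + x_normal.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    pooled_var = ss / df
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    s = np.sqrt(pooled_var) * c  # pooled-variance standard error of dm
    return dm, s, pooled_var, df, c


# ---------------------------------------------------------------------------
# SAM


def sam_statistic(x_tumor, x_normal, s0: float = 0.0) -> np.ndarray:
    """d_i = (mean_t - mean_n) / (s_i + s0) with pooled-variance s_i."""
    dm, s, *_ = _group_stats(x_tumor, x_normal)
    if s0 == 0.0 and np.any(s == 0.0):
        raise ValueError("zero variance feature with s0 = 0")
    return dm / (s + s0)


def default_s0(x_tumor, x_normal, percentile: float = 50.0) -> float:
    _, s, *_ = _group_stats(x_tumor, x_normal)
    return float(np.percentile(s, percentile))


def sam_test(
    x_tumor: np.ndarray,
    x_normal: np.ndarray,
    params: SamParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM d plus permutation q-values.

    For each feature's |d| cutoff, q = (median over label permutations of the
    count of permuted |d*| >= cutoff) / (observed count >= cutoff).
    """
    params = params or SamParams()
    x_tumor = np.atleast_2d(np.asarray(x_tumor, dtype=float))
    x_normal = np.atleast_2d(np.asarray(x_normal, dtype=float))
    n1 = x_tumor.shape[1]
    s0 = params.s0 if params.s0 is not None else default_s0(
        x_tumor, x_normal, params.s0_percentile
    )
    d = sam_statistic(x_tumor, x_normal, s0)
    pooled = np.hstack([x_tumor, x_normal])
    rng = np.random.default_rng(seed)
    n_total = pooled.shape[1]
    abs_d = np.abs(d)
    perm_counts = np.empty((params.n_perm, d.size))
    for b in range(params.n_perm):
        idx = rng.permutation(n_total)
        d_star = sam_statistic(pooled[:, idx[:n1]], pooled[:, idx[n1:]], s0)
        # permuted exceedance count at each feature's own |d| cutoff
        perm_counts[b] = np.searchsorted(
            np.sort(np.abs(d_star)), abs_d, side="left"
        )
        perm_counts[b] = d.size - perm_counts[b]
    observed = (np.sort(abs_d).searchsorted(abs_d, side="left") * -1) + d.size
    med_false = np.median(perm_counts, axis=0)
    q = np.minimum(med_false / np.maximum(observed, 1), 1.0)
    return pd.DataFrame({"d": d, "q": q, "s0": s0})


# ---------------------------------------------------------------------------
# Moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> ModTParams:
    """Method-of-moments fit of (d0, s0^2) on log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all features have zero variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) if e.size > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModTParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    x_tumor, x_normal, prior: ModTParams | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t with BH-adjusted p-values."""
    dm, _, pooled_var, df, c = _group_stats(x_tumor, x_normal)
    if prior is None:
        prior = fit_variance_prior(pooled_var, df)
    if np.isinf(prior.d0):
        s2_post = np.full_like(pooled_var, prior.s0_sq)
        df_post = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * pooled_var) / (prior.d0 + df)
        df_post = prior.d0 + df
    t = dm / (np.sqrt(s2_post) * c)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    p_adj = bh_adjust(p)
    return pd.DataFrame({"t": t, "p": p, "p_adj": p_adj, "df": df_post})


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# AUC


def auc_roc(values: np.ndarray, labels: np.ndarray) -> float | np.ndarray:
    """Mann-Whitney AUC of `values` for label 1 vs 0, ties counted half.

    ``values`` may be 1-D (one feature) or 2-D (features x samples).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    squeeze = values.ndim == 1
    mat = np.atleast_2d(values)
    aucs = np.empty(mat.shape[0])
    for i, row in enumerate(mat):
        ranks = stats.rankdata(row)
        r1 = ranks[labels == 1].sum()
        aucs[i] = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(aucs[0]) if squeeze else aucs


# ---------------------------------------------------------------------------
# Vote


@dataclass
class VoteThresholds:
    sam_q: float = 0.05
    modt_p_adj: float = 0.05
    auc_high: float = 0.8
    auc_low: float = 0.2


def differential_calls(
    data: pd.DataFrame,
    groups: pd.Series,
    sam_params: SamParams | None = None,
    thresholds: VoteThresholds | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run all three methods on a feature x sample matrix and vote.

    Returns one row per feature: statistics, per-method flags, ``vote`` and
    ``direction`` ('up' = higher in tumor).
    """
    thresholds = thresholds or VoteThresholds()
    tumor_ids = groups.index[groups == "tumor"]
    normal_ids = groups.index[groups == "normal"]
    xt = data[tumor_ids].to_numpy()
    xn = data[normal_ids].to_numpy()
    sam = sam_test(xt, xn, sam_params, seed=seed)
    modt = moderated_t(xt, xn)
    labels = np.concatenate([np.ones(len(tumor_ids), dtype=int), np.zeros(len(normal_ids), dtype=int)])
    auc = np.asarray(auc_roc(np.hstack([xt, xn]), labels))
    flag_sam = sam["q"].to_numpy() < thresholds.sam_q
    flag_modt = modt["p_adj"].to_numpy() < thresholds.modt_p_adj
    flag_auc = (auc >= thresholds.auc_high) | (auc <= thresholds.auc_low)
    votes = flag_sam.astype(int) + flag_modt.astype(int) + flag_auc.astype(int)
    direction = np.where(xt.mean(axis=1) - xn.mean(axis=1) >= 0, "up", "down")
    out = pd.DataFrame(
        {
            "d_sam": sam["d"].to_numpy(),
            "q_sam": sam["q"].to_numpy(),
            "t_mod": modt["t"].to_numpy(),
            "p_mod_adj": modt["p_adj"].to_numpy(),
            "auc": auc,
            "flag_sam": flag_sam,
            "flag_modt": flag_modt,
            "flag_auc": flag_auc,
            "vote": votes >= 2,
            "direction": direction,
        },
        index=data.index,
    )
    out.index.name = "feature"
    logger.info(
        "differential_calls: %d/%d features flagged by the 2-of-3 vote",
        int(out["vote"].sum()),
        len(out),
    )
    return out


def vote(
    flags_a: pd.Series, flags_b: pd.Series, flags_c: pd.Series
) -> pd.Series:
    """2-of-3 majority vote; all inputs must cover the same features."""
    if not (flags_a.index.equals(flags_b.index) and flags_a.index.equals(flags_c.index)):
        raise ValueError("vote: feature ids of the three methods differ")
    total = flags_a.astype(int) + flags_b.astype(int) + flags_c.astype(int)
    return total >= 2
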