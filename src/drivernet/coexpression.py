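"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, and average-linkage module detection with a static tree cut."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Cosmetic module-colour order used in reports; label 0 is always "grey".
MODULE_COLORS = [
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red",
    "black", "pink", "magenta", "purple", "greenyellow", "tan", "salmon",
]


def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(i,j)|^beta, zero diagonal.

    Constant genes get zero adjacency to everything (with a warning).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"adjacency: {int(constant.sum())} constant gene(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[np.isnan(cor)] = 0.0
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 0.0)
    adj = np.clip((adj + adj.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    return adj.sum(axis=1)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: tom_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij)
    off-diagonal with l_ij = sum_u a_iu a_uj, and tom_ii = 1."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(np.clip(t, 0.0, 1.0), index=adj.index, columns=adj.columns)


def detect_modules(
    tom_mat: pd.DataFrame, min_size: int = 25, cut_height: float = 0.25
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters below ``min_size`` get label 0 (unassigned / grey); surviving
    clusters are renumbered 1.. by decreasing size.
    """
    genes = tom_mat.index
    n = len(genes)
    if n < 2:
        return pd.Series(np.zeros(n, dtype=int), index=genes, name="module")
    dissim = 1.0 - tom_mat.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip(dissim, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = _relabel_by_size(raw, min_size)
    n_mod = labels.max()
    if n_mod == 0:
        warnings.warn("detect_modules: no cluster reached min_size; all genes unassigned",
                      stacklevel=2)
    logger.info("detect_modules: %d modules, %d/%d genes assigned",
                n_mod, int((labels > 0).sum()), n)
    return pd.Series(labels, index=genes, name="module")


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size]
    # decreasing size; ties broken by original label for determinism
    ordered = sorted(big.index, key=lambda c: (-big[c], c))
    mapping = {c: i + 1 for i, c in enumerate(ordered)}
    return np.array([mapping.get(c, 0) for c in raw], dtype=int)


def module_color(label: int) -> str:
    if label < len(MODULE_COLORS):
        return MODULE_COLORS[label]
    return f"module{label}"


def tighten_module(
    tom_mat: pd.DataFrame, module_genes: list[str], tom_quantile: float = 0.9
) -> pd.DataFrame:
    """Keep within-module gene pairs with TOM >= the given quantile (ties in).

    Returns an undirected edge table (gene_a, gene_b, tom), gene_a < gene_b.
    """
    if not 0.0 <= tom_quantile <= 1.0:
        raise ValueError("tom_quantile must be in [0, 1]")
    sub = tom_mat.loc[module_genes, module_genes].to_numpy(dtype=float)
    iu = np.triu_indices(len(module_genes), k=1)
    vals = sub[iu]
    if vals.size == 0:
        warnings.warn("tighten_module: module has < 2 genes", stacklevel=2)
        return pd.DataFrame(columns=["gene_a", "gene_b", "tom"])
    cutoff = np.quantile(vals, tom_quantile)
    keep = vals >= cutoff
    if not keep.any():
        warnings.warn("tighten_module: empty edge set", stacklevel=2)
    rows = [
        (module_genes[i], module_genes[j], v)
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep])
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom"])


def coexpression_edges(
    tom_mat: pd.DataFrame, modules: pd.Series, tom_threshold: float = 0.0
) -> pd.DataFrame:
    """Within-module undirected edge list with TOM weights above a floor."""
    rows = []
    for label in sorted(set(modules) - {0}):
        genes = list(modules.index[modules == label])
        sub = tom_mat.loc[genes, genes].to_numpy(dtype=float)
        iu = np.triu_indices(len(genes), k=1)
        for i, j in zip(*iu):
            if sub[i, j] > tom_threshold:
                rows.append((genes[i], genes[j], sub[i, j], label))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom", "module"])
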