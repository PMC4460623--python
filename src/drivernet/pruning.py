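"""Methylation-driven network pruning.

A downregulated gene whose expression profile anti-correlates with its
promoter methylation beyond a threshold is treated as epigenetically
silenced; regulatory edges into such genes are removed because TF binding is
unlikely to explain the downregulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


def expr_meth_correlation(
    expr: pd.DataFrame, meth: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Pearson r between expression and promoter methylation.

    Computed over the matched-sample intersection for genes present in both
    matrices; constant profiles are excluded with a warning.
    """
    samples = [s for s in expr.columns if s in set(meth.columns)]
    if len(samples) < 3:
        raise ValueError("need >= 3 matched samples")
    genes = [g for g in expr.index if g in set(meth.index)]
    rows = []
    skipped = 0
    for g in genes:
        x = expr.loc[g, samples].to_numpy(dtype=float)
        y = meth.loc[g, samples].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((g, r, len(samples)))
    if skipped:
        warnings.warn(f"expr_meth_correlation: {skipped} constant profile(s) excluded",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["gene", "r", "n_samples"]).set_index("gene")


@dataclass
class PruneResult:
    network: RegulatoryNetwork
    removed: pd.DataFrame  # source, target, directed, r
    silenced_genes: set[str]


def silenced_genes(
    correlations: pd.DataFrame, down_genes: set[str], threshold: float = 0.65
) -> set[str]:
    """Genes that are downregulated AND have r < -threshold (strict)."""
    anti = set(correlations.index[correlations["r"] < -threshold])
    return anti & down_genes


def prune(
    network: RegulatoryNetwork,
    correlations: pd.DataFrame,
    down_genes: set[str],
    threshold: float = 0.65,
    prune_undirected: bool = True,
    tfs: set[str] | None = None,
) -> PruneResult:
    """Remove edges explained away by promoter methylation.

    Every directed edge whose target is silenced is removed.  When
    ``prune_undirected`` is on, an undirected edge is removed iff exactly one
    endpoint is silenced and the other is a TF (the putative regulator).
    """
    sil = silenced_genes(correlations, down_genes, threshold)
    tfs = tfs or set()
    pruned = network.copy()
    removed_rows = []
    to_remove = []
    for key, e in pruned.edges.items():
        if e.directed:
            if e.target in sil:
                to_remove.append(key)
                removed_rows.append((e.source, e.target, True,
                                     float(correlations.loc[e.target, "r"])))
        elif prune_undirected:
            for sil_end, other in ((e.source, e.target), (e.target, e.source)):
                if sil_end in sil and other not in sil and other in tfs:
                    to_remove.append(key)
                    removed_rows.append((other, sil_end, False,
                                         float(correlations.loc[sil_end, "r"])))
                    break
    n = pruned.remove_edges(to_remove)
    logger.info("prune: removed %d edge(s) into %d silenced gene(s)", n, len(sil))
    removed = pd.DataFrame(removed_rows,
                           columns=["source", "target", "directed", "r"])
    return PruneResult(network=pruned, removed=removed, silenced_genes=sil)
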