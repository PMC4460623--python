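"""miRNA-mRNA network assembly with per-regulator hypergeometric filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .network import Edge, RegulatoryNetwork

logger = logging.getLogger(__name__)


def read_interaction_table(path: str | Path, kind: str) -> pd.DataFrame:
    """TSV with columns regulator, target (and optionally source).

    Duplicate (regulator, target) rows are collapsed on load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator", "target"} <= set(df.columns):
        raise ValueError(f"{path}: interaction table needs regulator, target columns")
    df = df.drop_duplicates(subset=["regulator", "target"]).reset_index(drop=True)
    df["kind"] = kind
    return df


def hypergeom_overrep(N: int, K: int, n: int, k: int) -> float:
    """One-sided over-representation p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class RegulatorTest:
    regulator: str
    N: int
    K: int
    n: int
    k: int
    p: float
    passed: bool


def mirna_to_mrna_edges(
    de_mirnas: set[str],
    target_table: pd.DataFrame,
    de_genes: set[str],
    measured_genes: set[str],
    p_threshold: float = 0.05,
) -> tuple[list[Edge], list[RegulatorTest]]:
    """miRNA -> target-gene edges for DE miRNAs whose target sets are
    enriched for DE genes.

    Universe = measured genes that carry at least one target annotation.
    """
    targets_by_mirna = target_table.groupby("regulator")["target"].agg(set)
    universe = set(target_table["target"]) & measured_genes
    N = len(universe)
    K = len(universe & de_genes)
    edges: list[Edge] = []
    tests: list[RegulatorTest] = []
    for m in sorted(de_mirnas):
        if m not in targets_by_mirna.index:
            logger.info("mirna_to_mrna_edges: %s has no annotated targets", m)
            continue
        targets = targets_by_mirna[m] & universe
        if not targets:
            logger.info("mirna_to_mrna_edges: %s has no measured targets", m)
            continue
        overlap = targets & de_genes
        p = hypergeom_overrep(N, K, len(targets), len(overlap))
        # p_threshold >= 1 disables the filter entirely
        passed = len(overlap) > 0 and (p < p_threshold or p_threshold >= 1.0)
        tests.append(RegulatorTest(m, N, K, len(targets), len(overlap), p, passed))
        if passed:
            for g in sorted(overlap):
                edges.append(Edge(m, g, True, ("mirna_target",), 1.0))
    return edges, tests


def tf_to_mirna_edges(
    de_mirnas: set[str],
    tf_mirna_table: pd.DataFrame,
    de_genes: set[str],
    p_threshold: float = 0.05,
) -> tuple[list[Edge], list[RegulatorTest]]:
    """TF -> miRNA edges for DE TFs whose regulated miRNAs are enriched for
    DE miRNAs.  Universe = miRNAs present in the table; only DE TFs enter."""
    mirnas_by_tf = tf_mirna_table.groupby("regulator")["target"].agg(set)
    universe = set(tf_mirna_table["target"])
    N = len(universe)
    K = len(universe & de_mirnas)
    edges: list[Edge] = []
    tests: list[RegulatorTest] = []
    for t in sorted(set(mirnas_by_tf.index) & de_genes):
        regulated = mirnas_by_tf[t]
        overlap = regulated & de_mirnas
        p = hypergeom_overrep(N, K, len(regulated), len(overlap))
        passed = len(overlap) > 0 and (p < p_threshold or p_threshold >= 1.0)
        tests.append(RegulatorTest(t, N, K, len(regulated), len(overlap), p, passed))
        if passed:
            for m in sorted(overlap):
                edges.append(Edge(t, m, True, ("tf_mirna",), 1.0))
    return edges, tests


@dataclass
class MergeSummary:
    n_mirnas: int
    n_genes: int
    n_mirna_mrna_links: int
    n_tf_mirna_links: int
    n_shared_genes: int
    n_shared_mirnas: int


def merge_networks(
    mirna_mrna_edges: list[Edge], tf_mirna_edges: list[Edge]
) -> tuple[RegulatoryNetwork, MergeSummary]:
    """Join the two edge sets into one typed network (duplicates collapse,
    keeping both provenance tags) and report paper-style node/link counts."""
    net = RegulatoryNetwork()
    for e in mirna_mrna_edges:
        net.add_node(e.source, "mirna")
        net.add_node(e.target, "gene")
        net.add_edge(e)
    for e in tf_mirna_edges:
        net.add_node(e.source, "tf")
        net.add_node(e.target, "mirna")
        net.add_edge(e)
    m_mirnas = {e.source for e in mirna_mrna_edges}
    m_genes = {e.target for e in mirna_mrna_edges}
    t_tfs = {e.source for e in tf_mirna_edges}
    t_mirnas = {e.target for e in tf_mirna_edges}
    summary = MergeSummary(
        n_mirnas=len(m_mirnas | t_mirnas),
        n_genes=len(m_genes | t_tfs),
        n_mirna_mrna_links=len(mirna_mrna_edges),
        n_tf_mirna_links=len(tf_mirna_edges),
        n_shared_genes=len(m_genes & t_tfs),
        n_shared_mirnas=len(m_mirnas & t_mirnas),
    )
    logger.info(
        "merge_networks: %d miRNAs, %d genes, %d + %d links",
        summary.n_mirnas, summary.n_genes,
        summary.n_mirna_mrna_links, summary.n_tf_mirna_links,
    )
    return net, summary
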