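"""Over-representation analysis and druggability flagging on user-supplied
annotation tables."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .differential import bh_adjust
from .mirna import hypergeom_overrep

logger = logging.getLogger(__name__)


def read_term_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns term_id, term_name, gene (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: term table needs term_id, gene columns")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df.drop_duplicates(subset=["term_id", "gene"])


def ora(
    study_set: Iterable[str],
    term_annotations: pd.DataFrame,
    universe: Iterable[str],
    min_study_annotated: int = 2,
    p_threshold: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the study set per term.

    A term is reported iff it covers >= ``min_study_annotated`` study genes
    and P(X >= k) < ``p_threshold`` (optionally BH-adjusted); output sorted
    by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("ora: empty universe")
    study = set(study_set)
    if not study <= universe:
        raise ValueError("ora: study set must be a subset of the universe")
    N, n = len(universe), len(study)
    rows = []
    for term_id, grp in term_annotations.groupby("term_id", sort=True):
        term_genes = set(grp["gene"]) & universe
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & study)
        p = hypergeom_overrep(N, K, n, k)
        rows.append({"term_id": term_id, "term_name": grp["term_name"].iloc[0],
                     "N": N, "K": K, "n": n, "k": k, "p": p})
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "N", "K", "n", "k", "p"])
    if df.empty:
        return df
    if bh_correct:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        signif = df["p_adj"] < p_threshold
    else:
        signif = df["p"] < p_threshold
    kept = df[(df["k"] >= min_study_annotated) & signif]
    kept = kept.sort_values(["p", "term_id"]).reset_index(drop=True)
    logger.info("ora: %d/%d terms enriched", len(kept), len(df))
    return kept


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, drug, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "drug"} <= set(df.columns):
        raise ValueError(f"{path}: drug table needs gene, drug columns")
    if "source" not in df.columns:
        df["source"] = Path(path).stem
    return df


def druggability(
    driver_genes: Sequence[str],
    drug_target_tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, float]:
    """Flag drivers with >= 1 drug-target record; per-source indicator columns.

    Returns (table, flagged fraction).
    """
    sources: list[str] = []
    targets_by_source: dict[str, set[str]] = {}
    for table in drug_target_tables:
        for source, grp in table.groupby("source"):
            targets_by_source.setdefault(str(source), set()).update(grp["gene"])
    sources = sorted(targets_by_source)
    rows = []
    for gene in sorted(set(driver_genes)):
        row: dict[str, object] = {"gene": gene}
        for src in sources:
            row[src] = int(gene in targets_by_source[src])
        row["druggable"] = any(gene in targets_by_source[s] for s in sources)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene", *sources, "druggable"])
    fraction = float(df["druggable"].mean()) if len(df) else 0.0
    logger.info("druggability: %d/%d drivers flagged (%.0f%%)",
                int(df["druggable"].sum()) if len(df) else 0, len(df), 100 * fraction)
    return df, fraction
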