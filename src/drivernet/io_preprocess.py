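"""Readers/writers for the external table formats and probe-level preprocessing.

Internal coordinate convention is 0-based half-open.  BED input is native;
1-based dialects (VCF, MAF-style TSV) are converted on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Annotation markers for probes that cannot be assigned to a single gene.
UNKNOWN = "UNKNOWN"
AMBIGUOUS = "AMBIGUOUS"

_MISSING_TOKENS = {"NA", "NaN", "nan", "N/A", ""}


class FormatError(ValueError):
    """Malformed external file (bad header, duplicate ids, non-numeric cell)."""


@dataclass
class ProbeMatrix:
    """Probe-level matrix (probes x samples) plus probe->gene annotation.

    ``gene_map`` may mark probes as :data:`UNKNOWN` or :data:`AMBIGUOUS`;
    probes absent from the map are treated as UNKNOWN.
    """

    values: pd.DataFrame
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GenomicFeature:
    """Genomic interval record, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    feature_class: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SomaticVariant:
    """Point variant, 0-based position; ``annotations`` pass through untouched."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    annotations: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"variant at {self.chrom}:{self.pos}: negative position")
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.chrom}:{self.pos}: ref == alt ({self.ref})")


@dataclass
class OmicsCohort:
    """Matched tumor/normal multi-omics matrices restricted to shared samples."""

    expression: pd.DataFrame
    methylation: pd.DataFrame
    mirna: pd.DataFrame
    variants: list[SomaticVariant]
    groups: pd.Series  # sample_id -> {"tumor", "normal"}

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    def sample_ids(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# Matrix I/O


def read_matrix(path: str | Path, gene_map: pd.Series | None = None) -> ProbeMatrix:
    """Read a TSV matrix (first column = probe/feature id, header = samples).

    Missing values may be encoded as NA/NaN/N-slash-A/empty; any other
    non-numeric cell is a hard error naming the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.columns.size == 0:
        raise FormatError(f"{path}: header row has no sample columns")
    if any(c == "" for c in raw.columns):
        raise FormatError(f"{path}: empty sample id in header")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        missing = cells.isin(_MISSING_TOKENS)
        parsed = pd.to_numeric(cells.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric cell {raw.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        values[col] = parsed
    logger.info("read_matrix %s: %d rows x %d samples", path.name, *values.shape)
    return ProbeMatrix(values=values, gene_map=gene_map)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_gene_map(path: str | Path) -> pd.Series:
    """Read a two-column probe->gene TSV (header ``probe\\tgene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (probe, gene)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")


def write_gene_map(gene_map: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"probe": gene_map.index, "gene": gene_map.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Probe collapsing


def collapse_probes(matrix: ProbeMatrix) -> pd.DataFrame:
    """Collapse probes to gene level by the mean of a gene's clean probes.

    Probes with any missing value, or annotated UNKNOWN/AMBIGUOUS (multiple
    genes count as ambiguous), are removed before averaging.
    """
    if matrix.gene_map is None:
        raise ValueError("collapse_probes requires probe->gene annotation")
    genes = matrix.gene_map.reindex(matrix.values.index).fillna(UNKNOWN)
    multi = genes.str.contains(r"[;,]", regex=True)
    bad_annot = genes.isin([UNKNOWN, AMBIGUOUS, ""]) | multi
    has_na = matrix.values.isna().any(axis=1)
    keep = ~(bad_annot | has_na)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "collapse_probes: dropped %d/%d probes (NA or unknown/ambiguous annotation)",
            n_dropped,
            len(keep),
        )
    clean = matrix.values.loc[keep]
    if clean.empty:
        raise ValueError("collapse_probes: no probes left after filtering")
    collapsed = clean.groupby(genes.loc[keep]).mean()
    collapsed.index.name = "gene"
    return collapsed


# ---------------------------------------------------------------------------
# Genomic features


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")[:2]
        sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))


def read_bed(path: str | Path, feature_class: str = "") -> list[GenomicFeature]:
    """Read BED (0-based half-open natively; name column = feature id)."""
    feats: list[GenomicFeature] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 else "."
        feats.append(
            GenomicFeature(chrom, start, end, strand, name, feature_class)
        )
    return feats


def write_bed(features: Iterable[GenomicFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


def validate_features(
    features: Sequence[GenomicFeature], chrom_sizes: Mapping[str, int]
) -> None:
    for f in features:
        if f.chrom not in chrom_sizes:
            raise ValueError(f"feature {f.feature_id}: chromosome {f.chrom} not in size table")
        if f.end > chrom_sizes[f.chrom]:
            raise ValueError(f"feature {f.feature_id}: end {f.end} beyond chromosome")


def filter_promoter_cpgs(
    cpg_features: Sequence[GenomicFeature],
    tss_table: Sequence[GenomicFeature],
    chrom_sizes: Mapping[str, int],
    half_window: int = 2000,
) -> tuple[list[GenomicFeature], pd.DataFrame]:
    """Keep CpG sites within +/- ``half_window`` bp (closed interval) of a TSS.

    Returns the retained CpGs plus a (cpg_id, gene_id, distance) assignment
    table; a CpG inside several promoters is assigned to every such gene.
    """
    for tss in tss_table:
        if tss.chrom not in chrom_sizes:
            raise ValueError(f"TSS {tss.feature_id}: chromosome {tss.chrom} not in size table")
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for tss in tss_table:
        by_chrom.setdefault(tss.chrom, []).append(tss)
    kept: list[GenomicFeature] = []
    rows: list[tuple[str, str, int]] = []
    for cpg in cpg_features:
        pos = cpg.start
        hit = False
        for tss in by_chrom.get(cpg.chrom, ()):
            dist = abs(pos - tss.start)
            if dist <= half_window:
                rows.append((cpg.feature_id, tss.feature_id, dist))
                hit = True
        if hit:
            kept.append(cpg)
    assignment = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "distance"])
    logger.info(
        "filter_promoter_cpgs: kept %d/%d CpGs (%d assignments)",
        len(kept),
        len(cpg_features),
        len(assignment),
    )
    return kept, assignment


# ---------------------------------------------------------------------------
# Variants


def read_variants(path: str | Path, dialect: str = "vcf") -> list[SomaticVariant]:
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "maf-tsv":
        return _read_maf_tsv(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_vcf(path: str | Path) -> list[SomaticVariant]:
    """Minimal plain-text VCF reader (positions converted to 0-based).

    Per-record sample id is carried in the INFO ``SAMPLE=`` key; other INFO
    keys are preserved as annotation columns.
    """
    variants: list[SomaticVariant] = []
    saw_header = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            saw_header = True
            continue
        if not line.strip():
            continue
        if not saw_header:
            raise FormatError(f"{path}: VCF data before #CHROM header line")
        parts = line.split("\t")
        if len(parts) < 8:
            raise FormatError(f"{path}: VCF record with {len(parts)} < 8 fields")
        chrom, pos, _vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
        info = parts[7]
        sample = ""
        annots: list[tuple[str, str]] = []
        if info != ".":
            for kv in info.split(";"):
                key, _, val = kv.partition("=")
                if key == "SAMPLE":
                    sample = val
                else:
                    annots.append((key, val))
        variants.append(
            SomaticVariant(chrom, pos - 1, ref, alt, sample, tuple(annots))
        )
    if not saw_header:
        raise FormatError(f"{path}: missing #CHROM header line")
    return variants


def write_vcf(
    variants: Iterable[SomaticVariant],
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            lines.append(f"##contig=<ID={chrom},length={size}>")
    lines.append('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info_parts = [f"SAMPLE={v.sample_id}"] if v.sample_id else []
        info_parts.extend(f"{k}={val}" for k, val in v.annotations)
        info = ";".join(info_parts) or "."
        lines.append(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}")
    Path(path).write_text("".join(l + "\n" for l in lines))


def _read_maf_tsv(path: str | Path) -> list[SomaticVariant]:
    """MAF-dialect TSV: chrom, pos (1-based), ref, alt, sample_id [+ extras]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in required]
    variants = []
    for row in df.itertuples(index=False):
        annots = tuple((c, getattr(row, c)) for c in extra_cols)
        variants.append(
            SomaticVariant(row.chrom, int(row.pos) - 1, row.ref, row.alt, row.sample_id, annots)
        )
    return variants


def write_maf_tsv(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    rows = [
        {"chrom": v.chrom, "pos": v.pos + 1, "ref": v.ref, "alt": v.alt,
         "sample_id": v.sample_id, **dict(v.annotations)}
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet + cohort alignment


def read_sample_sheet(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns sample_id, group")
    bad = set(df["group"]) - {"tumor", "normal"}
    if bad:
        raise FormatError(f"{path}: unknown group labels {sorted(bad)}")
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_sample_sheet(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def align_cohort(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    mirna: pd.DataFrame,
    variants: Sequence[SomaticVariant],
    sample_table: pd.Series,
    min_group_size: int = 3,
    require_variant_samples: bool = True,
) -> OmicsCohort:
    """Restrict all datasets to the samples common to every input.

    With ``require_variant_samples`` the variant table's sample set joins the
    intersection (the source study kept only samples present in all four
    datasets); disable when normals legitimately carry no variant records.
    """
    common = set(expr.columns) & set(meth.columns) & set(mirna.columns) & set(sample_table.index)
    if require_variant_samples:
        common &= {v.sample_id for v in variants}
    if not common:
        raise ValueError("align_cohort: no samples shared by all datasets")
    order = [s for s in sample_table.index if s in common]
    groups = sample_table.loc[order]
    for grp in ("tumor", "normal"):
        n = int((groups == grp).sum())
        if n < min_group_size:
            raise ValueError(f"align_cohort: group {grp!r} has {n} < {min_group_size} samples")
    kept_variants = [v for v in variants if v.sample_id in common]
    logger.info(
        "align_cohort: %d samples retained (%d tumor, %d normal)",
        len(order),
        int((groups == "tumor").sum()),
        int((groups == "normal").sum()),
    )
    return OmicsCohort(
        expression=expr[order],
        methylation=meth[order],
        mirna=mirna[order],
        variants=kept_variants,
        groups=groups,
    )
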