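"""Curated TF->gene seed edges plus a PWM promoter scanner.

The scanner uses log2-odds scores discretized to a fixed bin width; the null
score distribution is computed exactly by dynamic programming (per-column
convolution under an i.i.d. background), so scan p-values are exact with
respect to the discretized scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_SCORE_BIN = 0.05
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """Position probability matrix with a background model and discretized
    log2-odds scores."""

    motif_id: str
    probs: np.ndarray  # (4, L), columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_bin: float = DEFAULT_SCORE_BIN

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: PWM must be 4 x L with L >= 1")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        with np.errstate(divide="ignore"):
            lod = np.log2(self.probs) - np.log2(self.background[:, None])
        # integer scores on a fixed lattice; -inf cannot occur after pseudocounts
        self.int_scores = np.round(lod / self.score_bin).astype(np.int64)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def score_distribution(self) -> dict[int, float]:
        """Exact null distribution of the integer window score (DP over
        columns, i.i.d. background)."""
        dist: dict[int, float] = {0: 1.0}
        for j in range(self.length):
            nxt: dict[int, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = s + int(self.int_scores[b, j])
                    nxt[key] = nxt.get(key, 0.0) + p * self.background[b]
            dist = nxt
        return dist

    def score_pvalue(self, int_score: int) -> float:
        """P(window score >= int_score) under the background model."""
        dist = self.score_distribution()
        return float(sum(p for s, p in dist.items() if s >= int_score))

    def threshold_for_pvalue(self, p_threshold: float) -> int:
        """Smallest integer score whose tail probability is <= p_threshold."""
        dist = self.score_distribution()
        items = sorted(dist.items(), reverse=True)
        tail = 0.0
        thr = None
        for s, p in items:
            tail += p
            if tail <= p_threshold:
                thr = s
            else:
                break
        if thr is None:
            return int(max(dist) + 1)  # unreachable: no score is significant
        return thr


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                background: Sequence[float] | None = None) -> list[PWM]:
    """Read JASPAR plain-text count matrices (possibly several per file)."""
    bg = np.asarray(background if background is not None else [0.25] * 4)
    text = Path(path).read_text()
    pwms: list[PWM] = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if motif_id is not None and len(rows) == 4:
                counts = np.array([rows[b] for b in BASES], dtype=float)
                pwms.append(pwm_from_counts(motif_id, counts, pseudocount, bg))
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        elif line:
            base = line[0].upper()
            nums = line[line.index("[") + 1: line.index("]")] if "[" in line else line[1:]
            rows[base] = [float(tok) for tok in nums.replace(",", " ").split()]
    return pwms


def pwm_from_counts(motif_id: str, counts: np.ndarray,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    background: Sequence[float] | None = None) -> PWM:
    counts = np.asarray(counts, dtype=float) + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    bg = np.asarray(background if background is not None else [0.25] * 4)
    return PWM(motif_id=motif_id, probs=probs, background=bg)


def write_jaspar(pwms: Iterable[PWM], path: str | Path, scale: float = 100.0) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for b in range(4):
                vals = " ".join(f"{v:.0f}" for v in pwm.probs[b] * scale)
                fh.write(f"{BASES[b]} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip().upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Scanning


def best_hit_score(seq: str, pwm: PWM, both_strands: bool = True) -> int | None:
    """Best integer window score over (optionally) both strands.

    Windows containing non-ACGT letters are skipped.  Returns None when no
    scoreable window exists.
    """
    best: int | None = None
    strands = [seq, reverse_complement(seq)] if both_strands else [seq]
    L = pwm.length
    for strand in strands:
        idx = np.fromiter((_BASE_INDEX.get(c, -1) for c in strand), dtype=np.int64,
                          count=len(strand))
        for start in range(len(strand) - L + 1):
            window = idx[start:start + L]
            if (window < 0).any():
                continue
            score = int(pwm.int_scores[window, np.arange(L)].sum())
            if best is None or score > best:
                best = score
    return best


@dataclass(frozen=True)
class DirectedSeedEdge:
    tf: str
    target: str
    provenance: str  # "curated" | "motif"
    score: float | None = None


def mark_tfs(network_genes: Iterable[str], tf_tables: Sequence[Iterable[str]]) -> set[str]:
    """A gene is a TF iff it appears in at least one supplied TF table."""
    if not tf_tables:
        raise ValueError("mark_tfs: at least one TF table required")
    union: set[str] = set()
    for table in tf_tables:
        union |= set(table)
    return set(network_genes) & union


def curated_edges(
    coexpr_edges: pd.DataFrame,
    prior_tables: Sequence[pd.DataFrame],
    tfs: set[str],
) -> list[DirectedSeedEdge]:
    """Direct a co-expression link (TF, g) when a prior table knows TF->g.

    ``coexpr_edges`` needs columns gene_a/gene_b; priors need tf/target.
    Both orientations are emitted when both priors exist.
    """
    priors: set[tuple[str, str]] = set()
    for table in prior_tables:
        priors |= set(zip(table["tf"], table["target"]))
    edges: list[DirectedSeedEdge] = []
    seen: set[tuple[str, str]] = set()
    for a, b in zip(coexpr_edges["gene_a"], coexpr_edges["gene_b"]):
        for tf_gene, target in ((a, b), (b, a)):
            if tf_gene in tfs and (tf_gene, target) in priors and (tf_gene, target) not in seen:
                seen.add((tf_gene, target))
                edges.append(DirectedSeedEdge(tf_gene, target, "curated"))
    return edges


def pwm_scan(
    promoters: Mapping[str, str],
    pwms: Sequence[PWM],
    motif_to_tf: Mapping[str, str],
    network_genes: Iterable[str],
    tfs: set[str],
    p_threshold: float = 1e-4,
    non_acgt_tolerance: float = 0.1,
) -> list[DirectedSeedEdge]:
    """Scan every network gene's promoter with every TF's PWM.

    Emits one motif seed edge per (TF, gene) with a window whose exact-DP
    p-value is <= ``p_threshold``; self-edges are not emitted.
    """
    genes = [g for g in network_genes if g in promoters]
    edges: dict[tuple[str, str], DirectedSeedEdge] = {}
    for pwm in pwms:
        tf_gene = motif_to_tf.get(pwm.motif_id)
        if tf_gene is None or tf_gene not in tfs:
            continue
        thr = pwm.threshold_for_pvalue(p_threshold)
        for gene in genes:
            if gene == tf_gene:
                continue
            seq = promoters[gene]
            frac_bad = sum(c not in _BASE_INDEX for c in seq) / max(len(seq), 1)
            if frac_bad > non_acgt_tolerance:
                warnings.warn(f"pwm_scan: promoter of {gene} skipped "
                              f"({frac_bad:.0%} non-ACGT)", stacklevel=2)
                continue
            best = best_hit_score(seq, pwm)
            if best is not None and best >= thr:
                key = (tf_gene, gene)
                if key not in edges:
                    edges[key] = DirectedSeedEdge(
                        tf_gene, gene, "motif", score=best * pwm.score_bin
                    )
    logger.info("pwm_scan: %d motif seed edges", len(edges))
    return list(edges.values())


def read_prior_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf", "target"} <= set(df.columns):
        raise ValueError(f"{path}: prior table needs columns tf, target")
    return df
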