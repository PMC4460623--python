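"""Synthetic matched tumor/normal multi-omics cohort with planted ground
truth for every pipeline stage.

The cohort mirrors the source study's shape at desk scale: two sample
groups, log-scale expression with planted differential genes and planted
co-expression modules generated from known directed regulatory structures,
promoter methylation with a planted silenced-gene subset (strong
expression-methylation anti-correlation), differential miRNAs, somatic
variants with planted genomic proximity, and prior/target/drug/term tables
consistent with the planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drivers as _drivers
from . import io_preprocess as iop
from . import motifs as _motifs
from .network import Edge, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    # cohort shape
    n_tumor: int = 20
    n_normal: int = 20
    n_genes: int = 600
    n_mirnas: int = 120
    n_chroms: int = 3
    chrom_size: int = 5_000_000
    # expression
    n_modules: int = 4
    module_size: int = 30
    fraction_de: float = 0.25
    de_delta: float = 1.5
    base_mean: float = 8.0
    dag_weight: float = 0.95
    dag_extra_parent_prob: float = 0.3
    # methylation
    fraction_silenced: float = 0.3
    meth_noise_sd: float = 0.2
    meth_logit_sd: float = 0.8
    fraction_dm: float = 0.15
    dm_delta: float = 1.5
    dm_up_fraction: float = 2.0 / 3.0
    # miRNA
    fraction_de_mirna: float = 0.25
    mirna_delta: float = 1.5
    # variants / proximity
    n_variants: int = 60
    n_planted_mirna_proximal: int = 10
    n_planted_cpg_proximal: int = 12
    mirna_window: int = 250_000
    cpg_window: int = 3_000
    planted_distance_fraction: float = 0.1  # planted distance <= window * this
    # priors / tables
    curated_fraction: float = 0.6
    promoter_length: int = 500
    motif_length: int = 8
    mirna_targets_per_mirna: int = 15
    target_de_enrichment: float = 0.6
    tf_mirna_degree: int = 10
    tf_mirna_de_enrichment: float = 0.8
    drug_fraction: float = 0.25
    n_random_terms: int = 10

    def __post_init__(self) -> None:
        n_de = round(self.fraction_de * self.n_genes)
        if self.n_modules * self.module_size > n_de:
            raise ValueError(
                "infeasible config: module genes "
                f"({self.n_modules} x {self.module_size}) exceed DE genes ({n_de})"
            )
        if self.n_genes > self.n_chroms * (self.chrom_size // 24_000):
            raise ValueError("infeasible config: genes do not fit on the toy genome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class TruthBundle:
    de_genes: dict[str, str]          # gene -> up/down
    de_mirnas: dict[str, str]
    dm_genes: dict[str, str]          # gene -> up/down methylation
    module_assignment: dict[str, int]
    true_dag_per_module: dict[int, list[tuple[str, str]]]
    silenced_genes: list[str]
    planted_proximal_pairs: list[dict]
    planted_mds: dict[int, list[str]]
    tfs: list[str]
    prior_tables: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "de_mirnas": self.de_mirnas,
            "dm_genes": self.dm_genes,
            "module_assignment": self.module_assignment,
            "true_dag_per_module": {
                str(k): [list(e) for e in v] for k, v in self.true_dag_per_module.items()
            },
            "silenced_genes": self.silenced_genes,
            "planted_proximal_pairs": self.planted_proximal_pairs,
            "planted_mds": {str(k): v for k, v in self.planted_mds.items()},
            "tfs": self.tfs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        raw = json.loads(Path(path).read_text())
        return cls(
            de_genes=raw["de_genes"],
            de_mirnas=raw["de_mirnas"],
            dm_genes=raw["dm_genes"],
            module_assignment={g: int(m) for g, m in raw["module_assignment"].items()},
            true_dag_per_module={
                int(k): [tuple(e) for e in v] for k, v in raw["true_dag_per_module"].items()
            },
            silenced_genes=raw["silenced_genes"],
            planted_proximal_pairs=raw["planted_proximal_pairs"],
            planted_mds={int(k): v for k, v in raw["planted_mds"].items()},
            tfs=raw["tfs"],
        )


@dataclass
class SyntheticCohort:
    cohort: iop.OmicsCohort
    tss: list[iop.GenomicFeature]
    cpgs: list[iop.GenomicFeature]
    mirna_loci: list[iop.GenomicFeature]
    chrom_sizes: dict[str, int]
    promoters: dict[str, str]
    pwms: list[_motifs.PWM]
    motif_to_tf: dict[str, str]
    truth: TruthBundle


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_dag(
    genes: list[str], rng: np.random.Generator, extra_parent_prob: float
) -> list[tuple[str, str]]:
    """Two-hub DAG: node 1 hangs off node 0; every later node draws its
    parent(s) from the two hubs, keeping paths short so all within-module
    pairs stay strongly correlated."""
    edges: list[tuple[str, str]] = [(genes[0], genes[1])]
    for j in range(2, len(genes)):
        pool = genes[:2]
        first = pool[int(rng.integers(2))]
        parents = {first}
        if rng.random() < extra_parent_prob:
            parents = set(pool)
        for p in sorted(parents):
            edges.append((p, genes[j]))
    return edges


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Deterministically generate the full synthetic cohort and its truth."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(seed)
    (s_expr, s_meth, s_mirna, s_var, s_tables, s_motif) = [
        np.random.default_rng(s) for s in root.spawn(6)
    ]

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"mir-{i:03d}" for i in range(cfg.n_mirnas)]
    tumor = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    normal = [f"N{i:03d}" for i in range(cfg.n_normal)]
    samples = tumor + normal
    n_samples = len(samples)
    tumor_mask = np.array([1.0] * cfg.n_tumor + [0.0] * cfg.n_normal)
    groups = pd.Series(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
                       index=samples, name="group")

    # ----- differential truth ------------------------------------------------
    n_de = round(cfg.fraction_de * cfg.n_genes)
    de_gene_ids = list(s_expr.choice(cfg.n_genes, size=n_de, replace=False))
    de_gene_ids.sort()
    de_genes = [genes[i] for i in de_gene_ids]
    de_direction = {
        g: ("up" if s_expr.random() < 0.5 else "down") for g in de_genes
    }

    # modules are blocks of DE genes driven by a known DAG; all genes of a
    # module share one DE direction (co-regulation), alternating per module
    # so both silenced (down) and active (up) modules exist
    module_assignment: dict[str, int] = {}
    true_dags: dict[int, list[tuple[str, str]]] = {}
    offset = 0
    for label in range(1, cfg.n_modules + 1):
        block = de_genes[offset: offset + cfg.module_size]
        offset += cfg.module_size
        direction = "down" if label % 2 == 1 else "up"
        for g in block:
            module_assignment[g] = label
            de_direction[g] = direction
        true_dags[label] = _sample_dag(block, s_expr, cfg.dag_extra_parent_prob)

    # ----- expression --------------------------------------------------------
    expr = np.empty((cfg.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    signal = s_expr.normal(size=(cfg.n_genes, n_samples))  # background + roots
    for label in range(1, cfg.n_modules + 1):
        block = [g for g in de_genes if module_assignment.get(g) == label]
        parents_of: dict[str, list[str]] = {g: [] for g in block}
        for u, v in true_dags[label]:
            parents_of[v].append(u)
        w = cfg.dag_weight
        for g in block:  # block is in topological order by construction
            pars = parents_of[g]
            if pars:
                pmat = np.vstack([signal[gene_pos[p]] for p in pars])
                eps = s_expr.normal(size=n_samples)
                signal[gene_pos[g]] = w * pmat.mean(axis=0) + np.sqrt(1 - w * w) * eps
    for g in genes:
        row = gene_pos[g]
        shift = 0.0
        if g in de_direction:
            shift = cfg.de_delta * (1.0 if de_direction[g] == "up" else -1.0)
        expr[row] = cfg.base_mean + signal[row] + shift * tumor_mask
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)

    # ----- methylation -------------------------------------------------------
    down_module_targets = [
        g for g in de_genes
        if de_direction[g] == "down"
        and g in module_assignment
        and any(v == g for _, v in true_dags[module_assignment[g]])
    ]
    n_sil = round(cfg.fraction_silenced * len(down_module_targets))
    silenced = sorted(
        s_meth.choice(down_module_targets, size=n_sil, replace=False).tolist()
    )
    non_sil_pool = [g for g in genes if g not in set(silenced)]
    n_dm = round(cfg.fraction_dm * cfg.n_genes)
    dm_planted = sorted(s_meth.choice(non_sil_pool, size=n_dm, replace=False).tolist())
    dm_direction = {
        g: ("up" if s_meth.random() < cfg.dm_up_fraction else "down")
        for g in dm_planted
    }
    meth = np.empty((cfg.n_genes, n_samples))
    for g in genes:
        row = gene_pos[g]
        if g in set(silenced):
            x = expr[row]
            z = (x - x.mean()) / x.std()
            logit = 0.5 - 1.5 * z + s_meth.normal(0, cfg.meth_noise_sd, n_samples)
        else:
            logit = s_meth.normal(-0.5, cfg.meth_logit_sd, n_samples)
            if g in dm_direction:
                d = 1.0 if dm_direction[g] == "up" else -1.0
                logit = logit + cfg.dm_delta * d * tumor_mask
        meth[row] = _logistic(logit)
    meth_df = pd.DataFrame(meth, index=genes, columns=samples)
    # silenced genes are down in expression, hence up-methylated in tumor
    dm_genes = dict(dm_direction)
    dm_genes.update({g: "up" for g in silenced})

    # ----- miRNA expression --------------------------------------------------
    n_de_mir = round(cfg.fraction_de_mirna * cfg.n_mirnas)
    de_mirna_ids = sorted(s_mirna.choice(cfg.n_mirnas, size=n_de_mir, replace=False))
    de_mirnas = {
        mirnas[i]: ("up" if s_mirna.random() < 0.5 else "down") for i in de_mirna_ids
    }
    mirna_mat = s_mirna.normal(5.0, 1.0, size=(cfg.n_mirnas, n_samples))
    for m, direction in de_mirnas.items():
        row = mirnas.index(m)
        d = 1.0 if direction == "up" else -1.0
        mirna_mat[row] += cfg.mirna_delta * d * tumor_mask
    mirna_df = pd.DataFrame(mirna_mat, index=mirnas, columns=samples)

    # ----- toy genome --------------------------------------------------------
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_size for c in range(cfg.n_chroms)}
    chroms = list(chrom_sizes)
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    tss: list[iop.GenomicFeature] = []
    cpgs: list[iop.GenomicFeature] = []
    for i, g in enumerate(genes):
        chrom = chroms[i // genes_per_chrom]
        pos = 10_000 + (i % genes_per_chrom) * 24_000
        tss.append(iop.GenomicFeature(chrom, pos, pos + 1, "+", g, "gene_tss"))
        cpg_pos = pos + int(s_var.integers(-1500, 1501))
        cpgs.append(
            iop.GenomicFeature(chrom, cpg_pos, cpg_pos + 1, ".", f"cpg_{g}", "cpg_site")
        )
    # a few CpGs far from every promoter (dropped by the promoter filter)
    for j in range(30):
        i = int(s_var.integers(cfg.n_genes))
        chrom = chroms[i // genes_per_chrom]
        pos = 10_000 + (i % genes_per_chrom) * 24_000 + 12_000
        cpgs.append(
            iop.GenomicFeature(chrom, pos, pos + 1, ".", f"cpg_bg_{j:02d}", "cpg_site")
        )
    mirs_per_chrom = -(-cfg.n_mirnas // cfg.n_chroms)
    mir_spacing = max(1, (cfg.chrom_size - 40_000) // mirs_per_chrom)
    mirna_loci: list[iop.GenomicFeature] = []
    for i, m in enumerate(mirnas):
        chrom = chroms[i // mirs_per_chrom]
        pos = 22_000 + (i % mirs_per_chrom) * mir_spacing
        mirna_loci.append(
            iop.GenomicFeature(chrom, pos, pos + 80, "+", m, "mirna_locus")
        )

    # ----- somatic variants --------------------------------------------------
    bases = "ACGT"
    variants: list[iop.SomaticVariant] = []
    planted_pairs: list[dict] = []

    def _random_alt(ref: str) -> str:
        choices = [b for b in bases if b != ref]
        return choices[int(s_var.integers(3))]

    loci_by_id = {f.feature_id: f for f in mirna_loci}
    de_mirna_list = sorted(de_mirnas)
    for i in range(cfg.n_planted_mirna_proximal):
        m = de_mirna_list[i % len(de_mirna_list)]
        locus = loci_by_id[m]
        max_d = int(cfg.mirna_window * cfg.planted_distance_fraction)
        delta_bp = int(s_var.integers(1, max_d))
        pos = max(0, locus.start - delta_bp)
        ref = bases[int(s_var.integers(4))]
        v = iop.SomaticVariant(locus.chrom, pos, ref, _random_alt(ref), "")
        variants.append(v)
        planted_pairs.append(
            {"kind": "mirna", "chrom": v.chrom, "pos": v.pos,
             "ref": v.ref, "alt": v.alt, "feature_id": m}
        )
    cpg_by_gene = {f.feature_id[4:]: f for f in cpgs if f.feature_id.startswith("cpg_G")}
    dm_list = sorted(dm_genes)
    cpg_alts = ["T", "T", "G", "A"]  # C->T transitions most common
    for i in range(cfg.n_planted_cpg_proximal):
        g = dm_list[i % len(dm_list)]
        site = cpg_by_gene[g]
        max_d = max(2, int(cfg.cpg_window * cfg.planted_distance_fraction))
        pos = max(0, site.start - int(s_var.integers(1, max_d)))
        alt = cpg_alts[int(s_var.integers(4))]
        v = iop.SomaticVariant(site.chrom, pos, "C", alt, "")
        variants.append(v)
        planted_pairs.append(
            {"kind": "cpg", "chrom": v.chrom, "pos": v.pos,
             "ref": v.ref, "alt": v.alt, "feature_id": site.feature_id}
        )
    n_background = max(0, cfg.n_variants - len(variants))
    for _ in range(n_background):
        chrom = chroms[int(s_var.integers(cfg.n_chroms))]
        pos = int(s_var.integers(chrom_sizes[chrom]))
        ref = bases[int(s_var.integers(4))]
        variants.append(iop.SomaticVariant(chrom, pos, ref, _random_alt(ref), ""))
    # round-robin sample assignment so every cohort sample carries a record
    variants = [
        dataclasses.replace(v, sample_id=samples[i % n_samples])
        for i, v in enumerate(variants)
    ]

    # ----- TFs, priors, motifs ----------------------------------------------
    tfs = sorted({u for dag in true_dags.values() for u, _ in dag})
    curated_rows = []
    for label, dag in true_dags.items():
        for u, v in dag:
            if s_tables.random() < cfg.curated_fraction:
                curated_rows.append({"tf": u, "target": v, "source": "curated_db"})
    curated = pd.DataFrame(curated_rows, columns=["tf", "target", "source"])
    half = len(tfs) // 2
    tf_table_1 = pd.DataFrame({"gene": tfs[:half] or tfs})
    tf_table_2 = pd.DataFrame({"gene": tfs[half:] or tfs})

    promoters: dict[str, str] = {}
    for g in genes:
        promoters[g] = "".join(
            bases[i] for i in s_motif.integers(0, 4, cfg.promoter_length)
        )
    pwms: list[_motifs.PWM] = []
    motif_to_tf: dict[str, str] = {}
    hub_tfs = [dag[0][0] for dag in true_dags.values() if dag]
    for ti, tf_gene in enumerate(dict.fromkeys(hub_tfs)):
        consensus = "".join(bases[i] for i in s_motif.integers(0, 4, cfg.motif_length))
        counts = np.full((4, cfg.motif_length), 1.0)
        for j, c in enumerate(consensus):
            counts[bases.index(c), j] = 50.0
        motif_id = f"MOTIF{ti:02d}"
        pwms.append(_motifs.pwm_from_counts(motif_id, counts))
        motif_to_tf[motif_id] = tf_gene
        # plant the consensus site in the promoters of the TF's true targets
        label = module_assignment[tf_gene]
        for u, v in true_dags[label]:
            if u == tf_gene:
                seq = promoters[v]
                start = int(s_motif.integers(0, cfg.promoter_length - cfg.motif_length))
                promoters[v] = (
                    seq[:start] + consensus + seq[start + cfg.motif_length:]
                )

    # ----- miRNA target / TF->miRNA tables ----------------------------------
    de_gene_set = set(de_genes)
    non_de_genes = [g for g in genes if g not in de_gene_set]
    target_rows = []
    for m in mirnas:
        k = cfg.mirna_targets_per_mirna
        if m in de_mirnas and de_gene_set:
            n_hit = min(int(round(cfg.target_de_enrichment * k)), len(de_gene_set))
            picks = list(s_tables.choice(sorted(de_gene_set), n_hit, replace=False))
            picks += list(s_tables.choice(non_de_genes, k - n_hit, replace=False))
        else:
            picks = list(s_tables.choice(genes, k, replace=False))
        for g in picks:
            target_rows.append({"regulator": m, "target": g, "source": "target_db"})
    mirna_targets = pd.DataFrame(target_rows).drop_duplicates(
        subset=["regulator", "target"]
    )
    de_tf_pool = sorted(set(tfs) & de_gene_set) or tfs
    tf_mirna_rows = []
    de_mirna_set = set(de_mirnas)
    non_de_mirnas = [m for m in mirnas if m not in de_mirna_set]
    for t in de_tf_pool[:10]:
        deg = min(cfg.tf_mirna_degree, cfg.n_mirnas)
        n_hit = min(int(round(cfg.tf_mirna_de_enrichment * deg)), len(de_mirna_set))
        picks = list(s_tables.choice(sorted(de_mirna_set), n_hit, replace=False))
        picks += list(s_tables.choice(non_de_mirnas,
                                      min(deg - n_hit, len(non_de_mirnas)),
                                      replace=False))
        for m in picks:
            tf_mirna_rows.append({"regulator": t, "target": m, "source": "tfmir_db"})
    for t in (s_tables.choice(genes, 20, replace=False)):
        for m in s_tables.choice(mirnas, 4, replace=False):
            tf_mirna_rows.append({"regulator": t, "target": m, "source": "tfmir_db"})
    tf_mirna = pd.DataFrame(tf_mirna_rows).drop_duplicates(subset=["regulator", "target"])

    # ----- drug / term tables ------------------------------------------------
    n_drug = round(cfg.drug_fraction * cfg.n_genes)
    drug_genes = s_tables.choice(genes, n_drug, replace=False)
    drug_sources = ["drugdb_a", "drugdb_b", "drugdb_c"]
    drug_rows = [
        {"gene": g, "drug": f"drug_{i:03d}",
         "source": drug_sources[int(s_tables.integers(3))]}
        for i, g in enumerate(sorted(drug_genes))
    ]
    drugs = pd.DataFrame(drug_rows, columns=["gene", "drug", "source"])
    term_rows = []
    for label in range(1, cfg.n_modules + 1):
        members = [g for g, m in module_assignment.items() if m == label]
        extras = list(s_tables.choice(genes, 5, replace=False))
        for g in dict.fromkeys(members + extras):
            term_rows.append({"term_id": f"TERM_MOD{label}",
                              "term_name": f"module {label} process", "gene": g})
    for t in range(cfg.n_random_terms):
        for g in s_tables.choice(genes, 15, replace=False):
            term_rows.append({"term_id": f"TERM_RND{t:02d}",
                              "term_name": f"random process {t}", "gene": g})
    terms = pd.DataFrame(term_rows, columns=["term_id", "term_name", "gene"])

    # ----- planted MDS (verified dominating) ---------------------------------
    planted_mds: dict[int, list[str]] = {}
    for label, dag in true_dags.items():
        net = RegulatoryNetwork()
        for g, m in module_assignment.items():
            if m == label:
                net.add_node(g, "tf" if g in set(tfs) else "gene")
        for u, v in dag:
            net.add_edge(Edge(u, v, True, ("curated",), 1.0))
        mds = _drivers.mds_ilp(net)
        if not _drivers.is_dominating(net, mds):  # pragma: no cover - checker
            raise AssertionError(f"planted MDS for module {label} not dominating")
        planted_mds[label] = sorted(mds)

    truth = TruthBundle(
        de_genes=de_direction,
        de_mirnas=de_mirnas,
        dm_genes=dm_genes,
        module_assignment=module_assignment,
        true_dag_per_module=true_dags,
        silenced_genes=silenced,
        planted_proximal_pairs=planted_pairs,
        planted_mds=planted_mds,
        tfs=tfs,
        prior_tables={
            "curated": curated,
            "tf_table_1": tf_table_1,
            "tf_table_2": tf_table_2,
            "mirna_targets": mirna_targets,
            "tf_mirna": tf_mirna,
            "drugs": drugs,
            "terms": terms,
        },
    )
    cohort = iop.OmicsCohort(
        expression=expr_df.round(6),
        methylation=meth_df.round(6),
        mirna=mirna_df.round(6),
        variants=variants,
        groups=groups,
    )
    logger.info(
        "generate_cohort: %d genes (%d DE, %d silenced), %d miRNAs (%d DE), "
        "%d variants (%d planted proximal)",
        cfg.n_genes, len(de_genes), len(silenced), cfg.n_mirnas,
        len(de_mirnas), len(variants), len(planted_pairs),
    )
    return SyntheticCohort(
        cohort=cohort, tss=tss, cpgs=cpgs, mirna_loci=mirna_loci,
        chrom_sizes=chrom_sizes, promoters=promoters, pwms=pwms,
        motif_to_tf=motif_to_tf, truth=truth,
    )


def write_fixture(synth: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the exact external formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name: str, writer) -> None:
        path = out / name
        writer(path)
        paths[name] = path

    c = synth.cohort
    _save("expression.tsv", lambda p: iop.write_matrix(c.expression, p, "gene"))
    _save("methylation.tsv", lambda p: iop.write_matrix(c.methylation, p, "gene"))
    _save("mirna.tsv", lambda p: iop.write_matrix(c.mirna, p, "mirna"))
    _save("samples.tsv", lambda p: iop.write_sample_sheet(c.groups, p))
    _save("variants.vcf", lambda p: iop.write_vcf(c.variants, p, synth.chrom_sizes))
    _save("chrom.sizes", lambda p: iop.write_chrom_sizes(synth.chrom_sizes, p))
    _save("tss.bed", lambda p: iop.write_bed(synth.tss, p))
    _save("cpg.bed", lambda p: iop.write_bed(synth.cpgs, p))
    _save("mirna_loci.bed", lambda p: iop.write_bed(synth.mirna_loci, p))
    _save("promoters.fasta", lambda p: _motifs.write_fasta(synth.promoters, p))
    _save("motifs.jaspar", lambda p: _motifs.write_jaspar(synth.pwms, p))
    _save("motif_to_tf.tsv", lambda p: pd.DataFrame(
        {"motif_id": list(synth.motif_to_tf), "tf": list(synth.motif_to_tf.values())}
    ).to_csv(p, sep="\t", index=False))
    for name, table in synth.truth.prior_tables.items():
        _save(f"{name}.tsv", lambda p, t=table: t.to_csv(p, sep="\t", index=False))
    _save("truth.json", synth.truth.to_json)
    logger.info("write_fixture: %d files in %s", len(paths), out)
    return paths
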