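"""End-to-end orchestration: preprocess -> differential -> co-expression /
priors -> Bayesian GRN -> pruning -> miRNA network -> key drivers ->
proximity -> enrichment/druggability, with a deterministic run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    bayesnet,
    coexpression,
    differential,
    drivers,
    enrichment,
    io_preprocess as iop,
    mirna as mirna_mod,
    motifs,
    proximity as prox,
    pruning,
)
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All input paths and tunables; defaults follow the method's stated
    values where it states them (prune threshold 0.65, windows 250 kb / 3 kb,
    hypergeometric and ORA p < 0.05, 1000 permutations, 2-of-3 consensus)."""

    # inputs (a synthetic fixture directory provides all of these)
    expression: str = "expression.tsv"
    methylation: str = "methylation.tsv"
    mirna: str = "mirna.tsv"
    samples: str = "samples.tsv"
    variants: str = "variants.vcf"
    variant_format: str = "vcf"
    chrom_sizes: str = "chrom.sizes"
    tss_bed: str = "tss.bed"
    cpg_bed: str = "cpg.bed"
    mirna_loci_bed: str = "mirna_loci.bed"
    promoters_fasta: str = "promoters.fasta"
    pwm_file: str = "motifs.jaspar"
    motif_to_tf: str = "motif_to_tf.tsv"
    curated_priors: str = "curated.tsv"
    tf_tables: tuple[str, ...] = ("tf_table_1.tsv", "tf_table_2.tsv")
    mirna_targets: str = "mirna_targets.tsv"
    tf_mirna: str = "tf_mirna.tsv"
    drug_tables: tuple[str, ...] = ("drugs.tsv",)
    term_table: str = "terms.tsv"
    # tunables
    promoter_half_window: int = 2000
    beta: float = 6.0
    cut_height: float = 0.8
    min_module_size: int = 25
    bayes_size_cap: int = 150
    tighten_quantile: float = 0.9
    k_candidates: int = 8
    ess: float = 1.0
    max_parents: int = 4
    max_iter: int = 500
    arity: int = 3
    n_runs: int = 3
    min_support: int = 2
    prune_threshold: float = 0.65
    prune_undirected: bool = True
    mirna_window: int = 250_000
    cpg_window: int = 3_000
    hypergeom_p: float = 0.05
    ora_p: float = 0.05
    motif_p: float = 1e-4
    sam_n_perm: int = 100
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prune_threshold < 1:
            raise ValueError("prune_threshold must be in (0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_support > self.n_runs:
            raise ValueError("min_support cannot exceed n_runs")
        for name in ("mirna_window", "cpg_window", "n_perm", "k_candidates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("tf_tables", "drug_tables"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, na_rep="NA")


def run_all(config: PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> PipelineResult:
    """Execute every stage in dependency order; any stage error aborts with
    the failing stage named.  Identical config + seed reproduce identical
    outputs."""
    config.validate()
    in_dir = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.content_hash(), "seed": config.seed,
                      "stages": {}}
    stage = "preprocess"
    try:
        # ---- preprocess ----------------------------------------------------
        expr = iop.read_matrix(in_dir / config.expression).values
        has_meth = bool(config.methylation) and (in_dir / config.methylation).exists()
        if has_meth:
            meth = iop.read_matrix(in_dir / config.methylation).values
        else:
            warnings.warn(
                "methylation input missing: differential methylation, pruning "
                "and the CpG proximity analysis will be skipped", stacklevel=2,
            )
            meth = expr.iloc[0:0]
        mirna_expr = iop.read_matrix(in_dir / config.mirna).values
        sample_sheet = iop.read_sample_sheet(in_dir / config.samples)
        variants = iop.read_variants(in_dir / config.variants, config.variant_format)
        chrom_sizes = iop.read_chrom_sizes(in_dir / config.chrom_sizes)
        tss = iop.read_bed(in_dir / config.tss_bed, "gene_tss")
        cpgs = iop.read_bed(in_dir / config.cpg_bed, "cpg_site")
        mirna_loci = iop.read_bed(in_dir / config.mirna_loci_bed, "mirna_locus")
        cohort = iop.align_cohort(
            expr, meth if has_meth else expr, mirna_expr, variants, sample_sheet
        )
        if not has_meth:
            cohort.methylation = meth
        kept_cpgs, cpg_genes = iop.filter_promoter_cpgs(
            cpgs, tss, chrom_sizes, config.promoter_half_window
        )
        manifest["stages"][stage] = {
            "n_samples": len(cohort.samples),
            "n_tumor": len(cohort.sample_ids("tumor")),
            "n_normal": len(cohort.sample_ids("normal")),
            "n_genes": int(cohort.expression.shape[0]),
            "n_mirnas": int(cohort.mirna.shape[0]),
            "n_variants": len(cohort.variants),
            "n_promoter_cpgs": len(kept_cpgs),
        }

        # ---- differential --------------------------------------------------
        stage = "differential"
        sam_params = differential.SamParams(n_perm=config.sam_n_perm)
        expr_calls = differential.differential_calls(
            cohort.expression, cohort.groups, sam_params, seed=config.seed
        )
        meth_calls = (
            differential.differential_calls(
                cohort.methylation, cohort.groups, sam_params, seed=config.seed + 1
            )
            if has_meth
            else pd.DataFrame(
                columns=["d_sam", "q_sam", "t_mod", "p_mod_adj", "auc",
                         "flag_sam", "flag_modt", "flag_auc", "vote", "direction"]
            )
        )
        mirna_calls = differential.differential_calls(
            cohort.mirna, cohort.groups, sam_params, seed=config.seed + 2
        )
        _write_tsv(expr_calls, out / "differential_expression.tsv", True, "feature")
        _write_tsv(meth_calls, out / "differential_methylation.tsv", True, "feature")
        _write_tsv(mirna_calls, out / "differential_mirna.tsv", True, "feature")
        de_genes = set(expr_calls.index[expr_calls["vote"]])
        dm_genes = set(meth_calls.index[meth_calls["vote"]])
        de_mirnas = set(mirna_calls.index[mirna_calls["vote"]])
        down_genes = set(
            expr_calls.index[expr_calls["vote"] & (expr_calls["direction"] == "down")]
        )
        manifest["stages"][stage] = {
            "n_de_genes": len(de_genes),
            "n_dm_genes": len(dm_genes),
            "n_de_mirnas": len(de_mirnas),
        }

        # ---- co-expression -------------------------------------------------
        stage = "coexpression"
        de_expr = cohort.expression.loc[sorted(de_genes)]
        adj = coexpression.adjacency(de_expr, config.beta)
        tom_mat = coexpression.tom(adj)
        modules = coexpression.detect_modules(
            tom_mat, config.min_module_size, config.cut_height
        )
        _write_tsv(modules.to_frame(), out / "modules.tsv", True, "gene")
        module_edges: dict[int, pd.DataFrame] = {}
        for label in sorted(set(modules) - {0}):
            genes = sorted(modules.index[modules == label])
            if len(genes) > config.bayes_size_cap:
                edges = coexpression.tighten_module(
                    tom_mat, genes, config.tighten_quantile
                )
            else:
                edges = coexpression.tighten_module(tom_mat, genes, 0.0)
            module_edges[label] = edges
        manifest["stages"][stage] = {
            "n_modules": int(modules.max()),
            "n_assigned": int((modules > 0).sum()),
        }

        # ---- priors + motifs -----------------------------------------------
        stage = "priors"
        tf_tables = [
            pd.read_csv(in_dir / p, sep="\t", dtype=str)["gene"].tolist()
            for p in config.tf_tables
        ]
        curated_table = motifs.read_prior_table(in_dir / config.curated_priors)
        promoters = motifs.read_fasta(in_dir / config.promoters_fasta)
        pwms = motifs.read_jaspar(in_dir / config.pwm_file)
        m2t_df = pd.read_csv(in_dir / config.motif_to_tf, sep="\t", dtype=str)
        motif_to_tf = dict(zip(m2t_df["motif_id"], m2t_df["tf"]))
        seed_edges_per_module: dict[int, list[motifs.DirectedSeedEdge]] = {}
        all_tfs: set[str] = set()
        for label, edges in module_edges.items():
            genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
            tfs = motifs.mark_tfs(genes, tf_tables)
            all_tfs |= tfs
            seeds = motifs.curated_edges(edges, [curated_table], tfs)
            seeds += motifs.pwm_scan(
                promoters, pwms, motif_to_tf, genes, tfs, config.motif_p
            )
            # keep one edge per (tf, target); curated provenance wins
            dedup: dict[tuple[str, str], motifs.DirectedSeedEdge] = {}
            for e in seeds:
                dedup.setdefault((e.tf, e.target), e)
            seed_edges_per_module[label] = list(dedup.values())
        manifest["stages"][stage] = {
            "n_tfs": len(all_tfs),
            "n_seed_edges": sum(len(v) for v in seed_edges_per_module.values()),
        }

        # ---- Bayesian GRN --------------------------------------------------
        stage = "bayesian_grn"
        module_networks: dict[int, RegulatoryNetwork] = {}
        n_consensus = 0
        for label, edges in module_edges.items():
            genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
            seeds = seed_edges_per_module[label]
            seed_pairs = {(e.tf, e.target) for e in seeds}
            if len(genes) > config.bayes_size_cap:
                consensus_edges: dict[tuple[str, str], float] = {}
            else:
                data = bayesnet.discretize(
                    cohort.expression.loc[genes], config.arity
                )
                cands = bayesnet.sparse_candidates(
                    data, config.k_candidates, seed_pairs
                )
                consensus_edges, _ = bayesnet.learn_consensus(
                    data, seed_pairs, cands,
                    n_runs=config.n_runs, min_support=config.min_support,
                    base_seed=config.seed + label,
                    ess=config.ess, max_parents=config.max_parents,
                    max_iter=config.max_iter, arity=config.arity,
                )
            n_consensus += len(consensus_edges)
            module_networks[label] = bayesnet.assemble_grn(
                seeds, consensus_edges, edges, all_tfs
            )
        manifest["stages"][stage] = {"n_consensus_edges": n_consensus}

        # ---- pruning -------------------------------------------------------
        stage = "pruning"
        if has_meth:
            correlations = pruning.expr_meth_correlation(
                cohort.expression, cohort.methylation
            )
            _write_tsv(correlations, out / "expr_meth_correlation.tsv", True, "gene")
            removed_frames = []
            n_removed = 0
            for label in sorted(module_networks):
                result = pruning.prune(
                    module_networks[label], correlations, down_genes,
                    config.prune_threshold, config.prune_undirected, all_tfs,
                )
                module_networks[label] = result.network
                if not result.removed.empty:
                    removed = result.removed.copy()
                    removed["module"] = label
                    removed_frames.append(removed)
                n_removed += len(result.removed)
            removed_all = (
                pd.concat(removed_frames, ignore_index=True)
                if removed_frames
                else pd.DataFrame(columns=["source", "target", "directed", "r", "module"])
            )
            _write_tsv(removed_all, out / "pruned_edges.tsv")
            manifest["stages"][stage] = {"n_removed_edges": n_removed}
        else:
            warnings.warn("pruning skipped: no methylation data", stacklevel=2)
            manifest["stages"][stage] = {"skipped": True}
        for label, net in module_networks.items():
            net.write_tsv(out / f"grn_module_{label}.tsv")

        # ---- miRNA network -------------------------------------------------
        stage = "mirna_network"
        target_table = mirna_mod.read_interaction_table(
            in_dir / config.mirna_targets, "mirna_to_mrna"
        )
        tf_mirna_table = mirna_mod.read_interaction_table(
            in_dir / config.tf_mirna, "tf_to_mirna"
        )
        measured = set(cohort.expression.index)
        mm_edges, _ = mirna_mod.mirna_to_mrna_edges(
            de_mirnas, target_table, de_genes, measured, config.hypergeom_p
        )
        tm_edges, _ = mirna_mod.tf_to_mirna_edges(
            de_mirnas, tf_mirna_table, de_genes, config.hypergeom_p
        )
        mirna_net, summary = mirna_mod.merge_networks(mm_edges, tm_edges)
        mirna_net.write_tsv(out / "mirna_network.tsv")
        manifest["stages"][stage] = dataclasses.asdict(summary)

        # ---- key drivers ---------------------------------------------------
        stage = "key_drivers"
        per_module, gene_report = drivers.module_drivers(module_networks, modules)
        mirna_drivers = (
            drivers.mds_ilp(mirna_net) if mirna_net.nodes else set()
        )
        driver_genes = sorted(set().union(*per_module.values()) if per_module else set())
        driver_genes_mirna_net = sorted(
            m for m in mirna_drivers if mirna_net.node_types.get(m) != "mirna"
        )
        driver_mirnas = sorted(
            m for m in mirna_drivers if mirna_net.node_types.get(m) == "mirna"
        )
        _write_tsv(gene_report, out / "driver_genes.tsv")
        mirna_report = drivers.drivers_report(mirna_net, mirna_drivers)
        _write_tsv(mirna_report, out / "driver_mirna_network.tsv")
        all_driver_genes = sorted(set(driver_genes) | set(driver_genes_mirna_net))
        manifest["stages"][stage] = {
            "n_driver_genes_modules": len(driver_genes),
            "n_driver_genes_mirna_net": len(driver_genes_mirna_net),
            "n_driver_genes_total": len(all_driver_genes),
            "n_driver_mirnas": len(driver_mirnas),
        }

        # ---- proximity -----------------------------------------------------
        stage = "proximity"
        de_mirna_loci = [f for f in mirna_loci if f.feature_id in de_mirnas]
        mirna_cases = prox.find_proximal(
            de_mirna_loci, cohort.variants, config.mirna_window
        )
        dm_cpg_gene = dict(zip(cpg_genes["cpg_id"], cpg_genes["gene_id"]))
        dm_cpgs = [f for f in kept_cpgs if dm_cpg_gene.get(f.feature_id) in dm_genes]
        cpg_cases = (
            prox.find_proximal(
                dm_cpgs, cohort.variants, config.cpg_window, prox.CPG_GENOTYPES
            )
            if has_meth
            else []
        )
        prox_stats: dict = {
            "n_mirna_cases": len(mirna_cases),
            "n_cpg_cases": len(cpg_cases),
        }
        if mirna_cases:
            res = prox.permutation_test(
                mirna_cases, cohort.variants, chrom_sizes,
                config.n_perm, config.seed,
            )
            prox_stats["mirna_permutation_p"] = res.empirical_p
        if cpg_cases:
            dm_dirs = dict(
                meth_calls.loc[sorted(dm_genes), "direction"].items()
            )
            split = prox.split_by_methylation_direction(
                cpg_cases, dm_dirs, dm_cpg_gene
            )
            _write_tsv(split, out / "cpg_case_split.tsv", True, "methylation")
            prox_stats["n_up_methylated_cases"] = int(split.loc["up"].sum())
            prox_stats["n_down_methylated_cases"] = int(split.loc["down"].sum())
        excl = prox.exclusivity_check(
            mirna_cases, mirna_loci, de_mirnas, config.mirna_window
        )
        _write_tsv(excl, out / "mirna_case_exclusivity.tsv")
        _write_tsv(prox.cases_to_frame(mirna_cases), out / "mirna_proximity_cases.tsv")
        _write_tsv(prox.cases_to_frame(cpg_cases), out / "cpg_proximity_cases.tsv")
        manifest["stages"][stage] = prox_stats

        # ---- enrichment + druggability -------------------------------------
        stage = "enrichment"
        terms = enrichment.read_term_table(in_dir / config.term_table)
        universe = set(cohort.expression.index)
        module_frames = []
        for label in sorted(set(modules) - {0}):
            study = set(modules.index[modules == label]) & universe
            mod_enriched = enrichment.ora(
                study, terms, universe, p_threshold=config.ora_p
            )
            mod_enriched.insert(0, "module", label)
            module_frames.append(mod_enriched)
        enriched = (
            pd.concat(module_frames, ignore_index=True)
            if module_frames
            else pd.DataFrame(columns=["module", "term_id", "term_name",
                                       "N", "K", "n", "k", "p"])
        )
        _write_tsv(enriched, out / "module_enrichment.tsv")
        driver_study = set(all_driver_genes) & universe
        driver_enriched = enrichment.ora(
            driver_study, terms, universe, p_threshold=config.ora_p
        )
        _write_tsv(driver_enriched, out / "driver_enrichment.tsv")
        drug_tables = [
            enrichment.read_drug_table(in_dir / p) for p in config.drug_tables
        ]
        drug_df, fraction = enrichment.druggability(all_driver_genes, drug_tables)
        _write_tsv(drug_df, out / "driver_druggability.tsv")
        manifest["stages"][stage] = {
            "n_enriched_terms": len(enriched),
            "druggable_fraction": round(fraction, 6),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_text = json.dumps(manifest, indent=1, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(manifest_text.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run_all: complete -> %s", out)
    return PipelineResult(out_dir=out, manifest=manifest)
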