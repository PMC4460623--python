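# drivernet

Integrative network analysis of matched tumor/normal multi-omics cohorts:
differential calling, co-expression modules, Bayesian regulatory-network
inference, methylation-aware pruning, miRNA-mRNA network assembly, minimum
dominating-set key-driver detection, somatic-variant proximity analysis, and
enrichment/druggability reporting — plus a synthetic cohort generator with
planted ground truth so the entire pipeline is testable offline.

## What it does

Given gene-expression, promoter-methylation and miRNA-expression matrices
for tumor and normal samples plus a somatic-variant table, the pipeline:

1. **Preprocess** — collapse probes to gene level (mean of clean probes),
   keep promoter CpGs (±2 kb of a TSS), restrict to samples present in all
   datasets.
2. **Differential** — call differential features by three methods (SAM-style
   permutation statistic, empirical-Bayes moderated t, AUC-ROC) with a
   2-of-3 majority vote.
3. **Co-expression** — unsigned soft-threshold adjacency (|cor|^β),
   topological overlap, average-linkage modules with a static cut.
4. **Priors & motifs** — direct co-expression links using curated TF→gene
   tables; scan promoters with JASPAR PWMs (exact dynamic-programming score
   p-values) for motif seed edges.
5. **Bayesian GRN** — per-module hill climbing (add/remove/reverse/swap
   moves) under the BDe score with sparse mutual-information candidates;
   three tie-break-randomized runs, edges kept at ≥ 2/3 consensus and
   confirmed by a co-expression link.
6. **Pruning** — remove regulatory edges into downregulated genes whose
   expression anti-correlates with promoter methylation (r < −0.65):
   silencing explained by methylation, not TF binding.
7. **miRNA network** — miRNA→mRNA and TF→miRNA edges among differential
   features, filtered per regulator by a hypergeometric test (p < 0.05).
8. **Key drivers** — exact minimum dominating set per network via ILP
   (HiGHS), validated against a brute-force oracle.
9. **Proximity** — variants within 250 kb of dysregulated miRNA loci and
   C→A/C→G/C→T variants within 3 kb of differentially methylated promoter
   CpGs; significance by a chromosome-preserving position-permutation test
   with per-iteration Wilcoxon statistics.
10. **Enrichment & drugs** — hypergeometric over-representation of module
    genes against term tables (terms need ≥ 2 study genes); driver genes
    joined against drug-target tables.

## CLI

Every stage is a subcommand sharing plain-file interfaces (TSV matrices,
BED, VCF/MAF-TSV, FASTA, JASPAR, chrom.sizes):

```bash
# generate the synthetic fixture (all input files + planted truth)
drivernet synth --seed 1 --out-dir fixture/

# full pipeline
drivernet run --in-dir fixture/ --out run/ --seed 1

# individual stages
drivernet diff --matrix fixture/expression.tsv --samples fixture/samples.tsv --out calls.tsv
drivernet coexpr --matrix de_expr.tsv --out-modules modules.tsv --out-edges edges.tsv
drivernet priors --edges edges.tsv --prior-table fixture/curated.tsv \
    --tf-table fixture/tf_table_1.tsv --out seeds.tsv
drivernet grn --matrix module_expr.tsv --edges edges.tsv --seeds seeds.tsv --out grn.tsv
drivernet prune --network grn.tsv --expression fixture/expression.tsv \
    --methylation fixture/methylation.tsv --down-genes down.txt \
    --out pruned.tsv --out-removed removed.tsv
drivernet mirnanet --de-mirnas de_mirnas.txt --de-genes de_genes.txt \
    --measured-genes genes.txt --targets fixture/mirna_targets.tsv \
    --tf-mirna fixture/tf_mirna.tsv --out mirna_net.tsv
drivernet drivers --network grn.tsv --out drivers.tsv
drivernet proximity --features fixture/mirna_loci.bed --variants fixture/variants.vcf \
    --chrom-sizes fixture/chrom.sizes --window-bp 250000 --out cases.tsv
drivernet enrich --study drivers.txt --terms fixture/terms.tsv \
    --universe genes.txt --out enriched.tsv
drivernet drugs --drivers drivers.txt --drug-table fixture/drugs.tsv --out drugged.tsv
```

`drivernet run` writes per-stage TSV outputs and a `manifest.json` recording
the config hash, seed, and per-stage counts; identical config + seed
reproduce byte-identical output directories.

## Layout

```
src/drivernet/
  io_preprocess.py   readers/writers, probe collapse, promoter filter, cohort alignment
  synthetic.py       planted-truth cohort generator + fixture writer
  differential.py    SAM / moderated t / AUC + 2-of-3 vote
  coexpression.py    adjacency, TOM, module detection, tightening
  motifs.py          TF marking, curated seed edges, PWM scanner (exact DP p-values)
  bayesnet.py        discretization, BDe score, sparse candidates, hill climbing, consensus
  pruning.py         expression-methylation anti-correlation pruning
  mirna.py           hypergeometric-filtered miRNA-mRNA / TF-miRNA networks
  drivers.py         minimum dominating set (ILP + brute-force oracle), reports
  proximity.py       variant-feature proximity + permutation significance
  enrichment.py      over-representation analysis, druggability flags
  network.py         mixed directed/undirected typed network with provenance
  pipeline.py        end-to-end orchestration + manifest
  cli.py             click CLI (one subcommand per stage)
```
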