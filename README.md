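# momics-smr

Multi-omics QTL–GWAS causal inference toolkit: summary-data Mendelian
randomization (SMR) with HEIDI pleiotropy filtering, Bayesian colocalization,
multi-omics evidence-tier classification, tissue-level validation
bookkeeping, phenome-wide Wald-ratio screening, and hypergeometric gene-set
over-representation. A built-in summary-level simulator generates
LD-correlated cis-regions under controlled causal scenarios so every stage
runs and is testable fully offline.

## Modules

| module | what it does |
|---|---|
| `momics_smr.sumstats_io` | read/validate/harmonize per-SNP summary statistics, LD matrices, probe annotations; cis-window arithmetic |
| `momics_smr.simulate` | synthetic cis-regions (AR(1)/block LD), two-trait scenarios H0–H4, molecular causal chains (methylation → expression → protein/disease) |
| `momics_smr.smr` | instrument selection, SMR ratio test, HEIDI heterogeneity test, BH FDR, per-layer screening |
| `momics_smr.coloc` | Wakefield approximate Bayes factors, five-hypothesis posterior probabilities, exact enumeration oracle |
| `momics_smr.integrate` | gene tier classification from multi-layer evidence, cross-omics MR, tissue validation |
| `momics_smr.phemr_enrich` | phenome-wide Wald-ratio screen, hypergeometric over-representation (GMT input) |
| `momics_smr.pipeline` / `momics_smr.cli` | YAML-configured end-to-end orchestration with a hashed reproducibility manifest |
| `momics_smr.datasets` | bundled worked-example tables exercising the classification stages |

## Conventions

- Coordinates are 1-based with both-ends-inclusive intervals. BED-like probe
  annotation files (0-based half-open) are converted on load.
- Summary-statistics tables are delimited text with a header; canonical
  columns `snp, chr, pos, ea, oa, eaf, beta, se, p, n`. Other dialects
  (e.g. GCTA-COJO `.ma`) are mapped via a column-name schema dictionary.
- Harmonization aligns outcome effect alleles to the exposure, drops
  strand-ambiguous palindromic SNPs outright, and excludes SNPs whose
  effect-allele frequency differs by more than 0.2 between any pair of
  exposure, outcome and LD panel.
- p-value vs beta/se consistency is checked on load but only warns
  (published summary statistics often carry rounded p-values).

## CLI

```sh
momics-smr --version
momics-smr simulate chain --seed 1 --out sim/          # 4-layer causal chain
momics-smr simulate pair --hypothesis H4 --seed 1 --out pair/
momics-smr smr run --exposure sim/expression.tsv --outcome sim/disease.tsv \
    --ld sim/region.ld.tsv --probes sim/probes.bed --layer expr \
    --n-cases 25000 --n-controls 25000 --out smr.tsv
momics-smr coloc run --trait1 pair/trait1.tsv --trait2 pair/trait2.tsv \
    --probes probes.bed --trait2-type quantitative --out coloc.tsv
momics-smr integrate tiers --evidence evidence.tsv --out tiers.tsv
momics-smr integrate tissues --stats tissue_stats.tsv --out validation.tsv
momics-smr phemr run --instruments instruments.tsv --phenome phenome.tsv --out screen.tsv
momics-smr enrich run --query genes.txt --gmt sets.gmt --universe universe.txt --out ora.tsv
momics-smr run --config cfg.yaml --seed 1 --out out/   # full pipeline + manifest
```

The full pipeline writes per-stage TSVs plus `manifest.json` containing the
effective config, the seed, and a SHA-256 hash of every output; reruns with
the same config and seed are byte-identical.

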