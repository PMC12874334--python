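# lungomics

A multi-omics analysis toolkit for two-group (exposed vs vehicle), two-tissue
(normal vs tumor) mouse lung studies, plus a fully self-contained synthetic
study generator with planted ground truth.

## What it does

- **`lungomics.simulate`** — generates a toy study end to end: a 2-Mb random
  genome with a non-overlapping gene annotation (strand + TSS), CpG islands
  and 5-kb tiles, per-sample quartets of somatic caller VCFs with a designed
  consensus outcome, a sites-only known-germline VCF, negative-binomial
  RNA count/TPM matrices, and a CpG beta-value matrix. Planted effects
  (DEGs, promoter DMS, and inversely coupled "epigenetically controlled"
  genes — 12 activated + 8 repressed by default) are recorded in a JSON
  truth table for exact recovery scoring.
- **`lungomics.mutations`** — merges per-caller VCFs by
  (chrom, pos, ref, alt) and applies the fixed somatic filter chain:
  consensus (≥ 2 of 4 callers) → known-germline-site removal (allele-exact)
  → shared-across-samples removal → clustered-mutation removal (> 3
  variants within a 10-bp span). Computes mutations/Mb burden and
  Welch-tests it between groups.
- **`lungomics.spectra`** — SBS96 / DBS78 / ID83 classification from
  reference context (pyrimidine-centric strand collapsing, canonical
  doublet orientation, left-aligned indels with homopolymer, repeat-unit
  and microhomology bins), SigProfiler-style matrices, cosine similarity.
- **`lungomics.expression`** — row-sum count filter, median-of-ratios size
  factors, TMM factors, a simplified per-gene negative-binomial Wald test
  (method-of-moments dispersion, no shrinkage/outlier handling; p-values
  use a t reference with n−2 df as a small-sample correction), gene-module
  mean z-scores, preranked GSEA (weighted KS running sum, gene-label
  permutations), and marker-set deconvolution scores.
- **`lungomics.methylation`** — site/region differential methylation:
  effect on the beta scale (Δβ), testing on M-values, stabilized log2 mean
  quotient, hyper/hypo calls at |Δβ| ≥ 0.2 & p < 0.05, and region
  aggregation (promoters, gene bodies, CpG islands, tiles).
- **`lungomics.integration`** — promoter map (−1.5 kb/+0.5 kb around the
  TSS, strand-aware), DMG derivation from differential promoter CpGs,
  five-way quadrant classification (|log2FC| ≥ 1 RNA, ≥ 0.1 methylation),
  and the inverse-correlation screen (Pearson r ≤ −0.6, p < 0.1 across the
  treated samples) yielding epigenetically activated/repressed gene lists.
- **`lungomics.pipeline`** — orchestrates all six stages from one YAML
  config with a single seed and writes a manifest with sha256 digests of
  every output; reruns are byte-identical.

## CLI

One entry point with one subcommand per stage:

```bash
lungomics simulate  --seed 1 --outdir sim/
lungomics mutations --vcf-dir sim/vcf --callers mutect2,varscan2,strelka2,muse \
    --known-sites sim/known_sites.vcf --callable-mb 2.0
lungomics spectra   --mutations mutations.tsv --ref sim/reference.fa
lungomics expression --counts sim/counts.tsv --tpm sim/tpm.tsv \
    --design sim/design.tsv --gene-sets sim/gene_sets.gmt --markers sim/markers.gmt
lungomics methylation --beta sim/beta.tsv --sites sim/cpg_sites.tsv \
    --design sim/design.tsv --regions islands=sim/cpg_islands.bed,tiles=sim/tiles.bed
lungomics integrate --de expression_de_normal.tsv --meth methylation_sites_normal.tsv \
    --annotation sim/annotation.tsv --beta sim/beta.tsv --expr sim/counts.tsv \
    --sites sim/cpg_sites.tsv --design sim/design.tsv --tissue normal --group HDM
lungomics run-all   --config run.yaml          # everything, one seed
```

`run.yaml` accepts any `RunConfig` field (thresholds default to the study
values) and a `simulation:` block with `SimulationConfig` fields.

## Curated gene sets

`src/lungomics/datasets/gene_sets.gmt` ships the curated IL-1/inflammasome
and IL-17 target modules used for module scoring and GSEA on real data; the
simulator emits its own stand-in module and marker GMTs for synthetic runs.
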