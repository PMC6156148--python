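# airechrom

Tools for asking whether the chromatin state around a gene's transcription
start site predicts how the gene responds to AIRE, the transcriptional
facilitator that drives promiscuous gene expression in medullary thymic
epithelial cells (mTEC). AIRE-induced genes (undetected or strongly
increased without/with AIRE) carry elevated repressive marks (H3K27me3,
H3K9me3) and depleted active marks (H3K4me3, H3K9ac) at their promoters
relative to AIRE-independent genes; `airechrom` implements the full
analysis that quantifies, visualises and classifies this signature, and a
synthetic-data generator that reproduces its statistical structure so every
stage is testable without any sequencing data.

The package is aimed at computational immunologists and regulatory
genomicists who want a reproducible, dependency-light reimplementation of
this analysis style: bedGraph/BED in, TSVs out, one seeded pipeline.

## What it computes

* **TSS chromatin features** — per gene and mark, the maximum
  library-scaled ChIP/input ratio within 1 kb of any transcript TSS
  (`(chip + c) / (input + c)` piecewise, values scaled to counts per
  million, pseudocount `c = 0.5`).
* **Metagene profiles** — median ratio per strand-oriented distance bin
  around the TSS, by AIRE category.
* **Tissue specificity** — tau, `τ = Σᵢ(1 − x̂ᵢ)/(n − 1)` with
  `x̂ᵢ = xᵢ/max(x)`; genes with `τ ≥ 0.8` are tissue-restricted antigens
  (TRAs).
* **Single-cell detection** — DESeq median-of-ratios size factors, per-cell
  OLS of log₁₀(ERCC spike-in molecules) on log₁₀(adjusted expression), and
  the per-gene proportion of cells with ≥ 1 estimated molecule; AIRE-induced
  genes are matched one-to-one to independent TRAs detected in a nearly
  identical fraction of cells (±0.6%).
* **Classification** — an ensemble (default 100 runs) of single-hidden-layer
  neural networks (logistic units, SSE loss, full-batch gradient descent,
  stop at < 0.01 SSE improvement per epoch) trained on 67% of genes to call
  AIRE-induced vs AIRE-independent, reporting test accuracy, the
  label-resampling **null accuracy** (closed form `Σ p_c²`), and **Olden
  connection-weight importances** (`Σ_h W_ih·w_ho`, scaled to [−1, 1]).
* **Chromatin PCA** — correlation-matrix PCA of the feature matrix with
  Spearman correlations of PC1 against detection proportion and tau.
* **Interval enrichment** — fold enrichment of peak overlap with gene ± 5 kb
  neighbourhoods against length-preserving random placement in a workspace
  (default 10,000 randomisations), with empirical p and BH q-values.

## Worked example

Every input is synthesised from a plain-text config. The generator plants a
known signature — repressive marks up, active marks down around
AIRE-induced TSSs — so the downstream estimates have known targets:

```bash
cat > config.txt <<'CFG'
n_genes = 300
seed = 4
n_cells = 100
n_tissues = 8
chrom_lengths.chr1 = 12000000
pipeline.classify_runs = 20
pipeline.enrich_n_rand = 1000
CFG
airechrom run --config config.txt --outdir out
```

All nine stages report `ok` and `out/` then contains the feature matrix,
metagene profiles, tau table, detection proportions, matched pairs,
classifier report, PCA and enrichment TSVs plus a checksummed
`manifest.json` (re-running skips unchanged stages). Key numbers from this
run:

* `out/classifier_summary.tsv` — mean accuracy **0.923** vs mean null
  accuracy **0.681** (Wilcoxon p ≈ 0.01 over 20 runs): the planted
  chromatin signature predicts AIRE status far better than label
  resampling. H3K27me3 has the largest positive Olden importance
  (mean **+0.74**, p < 1e-4) and H3K27ac/H3K4me3 negative ones — the
  planted directions.
* `out/pca_summary.tsv` — PC1 explains **54%** of feature variance and
  anticorrelates with single-cell detection (Spearman ρ = **−0.43**,
  p ≈ 1e-14): genes with repressive promoters are expressed in fewer cells.
* `out/enrichment.tsv` — peaks simulated with a 3× placement preference for
  gene neighbourhoods come back **1.83-fold** enriched (p ≈ 0.002 at 1,000
  randomisations); the fold is diluted below 3 because gene ± 5 kb intervals
  cover ~30% of this toy genome.

The same stages are available as individual subcommands
(`simulate`, `features`, `metagene`, `tau`, `detect`, `match`, `classify`,
`pca`, `enrich`) for real bedGraph/BED/TSV inputs.

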