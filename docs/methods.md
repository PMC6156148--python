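# Methods

This note records the models, conventions and numerical choices behind
`airechrom`, in the order the pipeline runs. It documents what each stage
assumes and what the synthetic generator does and does not emulate; every
number quoted as an outcome here is computed by the test suite or the
acceptance script, not asserted by hand.

## Coordinates and track algebra

All genomic coordinates are 0-based half-open (BED/bedGraph convention).
A signal track is a per-chromosome list of sorted, non-overlapping
`[start, end)` intervals with a value and a library size; values are scaled
to a nominal library of 10⁶ fragments (counts-per-million style) before any
ratio is formed. Replicates are pooled by summing values piecewise and
summing library sizes before scaling.

The ChIP/input ratio is computed piecewise over the union of both tracks'
breakpoints as `(chip + c)/(input + c)` with pseudocount `c = 0.5` per
library-scaled unit (the analysis this reimplements does not state one; 0.5
is half the smallest meaningful scaled count). Regions covered by neither
track are assigned the neutral ratio 1, so missing input coverage neither
inflates nor deflates a gene's feature.

A TSS window of half-width `w` (default 1,000 bp) is the closed interval of
`2w + 1` bases centred on the TSS base, clipped at chromosome edges. The
per-gene feature is the maximum ratio over the union of windows across all
of the gene's transcript TSSs; maxima need no tie-break. Metagene profiles
average the ratio within `bin` bp bins (default 50) of the strand-oriented
±5 kb window of each gene's primary TSS — negative-strand genes are flipped
so upstream is negative — then take the per-category median across genes.
The ±5 kb width mirrors the gene ± 5 kb convention used by the enrichment
analysis; the window statistics are verified base-for-base against naive
per-base scans on random toy tracks.

## Tau tissue specificity

`τ = Σᵢ (1 − x̂ᵢ)/(n − 1)` with `x̂ᵢ = xᵢ/max(x)` over `n ≥ 2` tissues,
applied to expression values as given (no log transform; τ is invariant to
linear rescaling anyway). All-zero genes have no defined τ; they are
flagged, excluded from TRA calls, and never silently imputed. The TRA call
is `τ ≥ 0.8`, boundary inclusive.

## Single-cell detection and matching

Counts are adjusted by DESeq median-of-ratios size factors. The reference
set is every row — gene or ERCC spike-in — with a non-zero count in all
cells; in sparse single-cell data this reference is typically dominated by
the abundant spike-ins, which is standard for plate-based protocols. An
empty reference is an error rather than a silent pseudo-reference fallback.

Absolute molecule abundance is calibrated per cell by ordinary least
squares of log₁₀(known spike-in molecules) on log₁₀(adjusted counts), using
only spike-ins detected in that cell; log–log is the conventional scale for
ERCC dose–response. Cells with fewer than three detected spike-ins are
flagged uncalibratable and dropped. A gene is "detected" in a cell when its
estimated molecules are ≥ 1 (continuous estimate thresholded, with a 1e-9
log₁₀ slack so exact-boundary estimates count); the detection proportion is
the fraction of calibratable cells detecting the gene.

Matching processes AIRE-induced genes in seeded random order and pairs each
uniformly at random, without replacement, with a candidate independent TRA
whose detection proportion differs by at most 0.006 — one cell's worth of
resolution at 167 cells, exposed as a parameter. Induced genes with no
viable partner are discarded and reported. By construction the matched set
is balanced, so its label-resampling null accuracy is 50%.

## Classifier ensemble

The classifier is a single-hidden-layer feedforward network: logistic
activations on hidden and output units, sum-of-squared-errors loss,
features standardised to zero mean and unit variance on the training set.
Training is full-batch gradient descent on the mean-SSE gradient with
learning rate 0.05 and classical momentum 0.9, stopping when the decrease
in training SSE between successive epochs falls below 0.01 (evaluated
after a 100-epoch floor, so the rule measures post-plateau progress rather
than the flat start; without the floor and momentum, plain small-step
descent stalls on its initial plateau and stops untrained). Maximum 10,000
epochs; a non-finite loss marks the run failed — failed runs are excluded
and logged, never silently retried, and more than 20% failures aborts the
ensemble.

Each of the (default 100) runs draws a fresh uniform 67/33 train/test
split. The hidden-layer size is re-selected per run from candidates
`1 … ⌈0.8·n_inputs⌉ − 1` (fewer than 80% of the input count; 8 marks give
1–6) by accuracy on an inner 75/25 validation split of the training set,
ties resolved toward the smaller network. The output threshold is chosen
on the training set as the observed output value maximising balanced
accuracy (robust to class imbalance), smallest threshold on ties; with
degenerate single-class training labels it falls back to 0.5 with a
warning.

Null accuracy is the accuracy of predictions drawn i.i.d. from the
empirical test-label distribution, averaged over (default 1,000)
resamplings; its expectation is `Σ_c p_c²` and the resampled estimate is
checked against that closed form. Olden importances sum the products of
input→hidden and hidden→output weights per input (bias weights excluded)
and scale by the maximum absolute value, preserving sign; sum-absolute
scaling is available as an option. Across runs, accuracy vs null accuracy
and each input's importances vs zero are tested with two-sided Wilcoxon
signed-rank tests.

## Chromatin PCA

PCA uses the correlation matrix by default (`scale=True`) because marks
differ in dynamic range; a zero-variance column is an error naming the
column. Components come from the SVD of the centred (scaled) matrix, with
the deterministic sign convention that each rotation's largest-magnitude
element is positive. For covariate correlations PC1 is additionally
oriented to correlate positively with the mean repressive-mark feature
(H3K27me3, H3K9me3), so "high PC1" always reads as repressive chromatin;
Spearman correlations use average ranks for ties and the t-approximation
for p-values.

## Interval enrichment

Peak, annotation and workspace interval sets are canonicalised (sorted,
bookended/overlapping intervals merged). The observed statistic is the
base-pair overlap of peaks (clipped to the workspace) with the annotation
(intersected with the workspace). Each randomisation re-places every peak,
length preserved, uniformly at random in the concatenated workspace;
placements are independent, so randomised peaks may overlap each other —
a deliberate simplification that keeps the statistic while avoiding
segment-sampling bookkeeping. Fold is observed over mean randomised
overlap; the empirical two-sided p-value is
`min(1, 2·min(#{rand ≥ obs}+1, #{rand ≤ obs}+1)/(n_rand+1))`, which is
super-uniform under the null by construction. Peaks longer than the
workspace are clipped with a warning; expected overlap of zero flags the
fold undefined. Benjamini–Hochberg q-values are provided for families of
tests.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes,
not the sequencing process: no reads, duplicates, mappability or
peak-caller artefacts.

* **Genome and genes.** Default 2,000 genes on two chromosomes (30 + 20
  Mb). Primary TSSs are placed uniformly with a guaranteed minimum spacing
  of `2·window + 300` bp so neighbouring genes can never share feature
  windows (real genomes violate this; fixtures need clean attribution).
  Extra transcript TSSs sit within 300 bp downstream. Gene bodies extend
  2 kb from the TSS.
* **Tracks.** Signal is simulated in 50 bp bins over TSS ± 6 kb regions.
  Input is baseline 20 (library-scaled) with lognormal bin noise
  (sd 0.02); ChIP multiplies the baseline by `exp(a_g · g(d))` where
  `g(d)` is a Gaussian of sd 300 bp in the distance from the bin to the
  TSS and the per-gene amplitude `a_g` is the planted per-category
  log-shift plus N(0, 0.1). The bin containing the TSS carries the full
  amplitude, so in the noiseless limit the TSS ratio is exactly
  `exp(shift)`. Default shifts follow the mTEC signature — H3K27me3 +1.2
  and H3K9me3 +1.0 in AIRE-dependent genes (smaller in AIRE-enhanced),
  ATAC and H3K4me1 mildly up, H3K4me3 −1.2, H3K9ac/H3K27ac/H3K4ac down —
  chosen to make the category separation visible at desk scale, not to
  match any real effect size quantitatively.
* **Atlas.** 19 tissues. Tissue-restricted categories express in one
  random tissue with the rest at Uniform(0, 0.2) of the maximum
  (τ ≈ 0.9); other genes are near-uniform (τ ≈ 0.23).
* **Single cells.** 167 cells (one cell ≈ 0.6% detection resolution).
  True detection proportions are Beta-distributed per category — induced
  genes detected in few cells (means ≈ 0.05–0.10), independent TRAs
  similar-to-slightly-higher, housekeeping-like genes in most cells —
  giving the negative PC1–detection and positive PC1–τ correlations their
  direction. Detected entries get 1 + NB(2, 0.5) counts (only the derived
  detection proportion matters downstream, so the count model is free).
  92 ERCC spike-ins span 1–10⁴ molecules log-uniformly; counts are 10%
  capture with lognormal noise, rounded.
* **Peaks.** Fixed 200 bp peaks with start density proportional to the
  enrichment factor inside gene ± 5 kb regions and 1 elsewhere; factor 1
  reproduces the randomiser's null exactly, which is what makes the
  p-value calibration check exact.
* **Seeding.** One master seed fans out to fixed per-stage substreams
  (spawn keys), so partial runs and full runs agree byte-for-byte.

## Problem sizes used by the checks

The test suite runs the classifier ensemble at its study conditions
(2,000 genes × 8 marks, 100 runs) and the zero-effect control at 20 runs
with balanced categories — balanced because a noise-level classifier only
matches the resampling null when `Σ p_c² = 0.5`; the matched design is the
balanced case. Enrichment calibration uses 1,000 null data sets of 30
peaks on a 0.5 Mb toy genome at 1,000 randomisations each; the benchmark
script uses 600 genes and 167 cells. These sizes were chosen as the
smallest at which the targeted effects are comfortably resolved.

## Known limitations

* The generator's effect sizes, noise levels and detection models are
  stylised; passing tests demonstrate that the pipeline recovers what was
  planted under clean conditions, not that real mTEC data would yield the
  same accuracies or correlations.
* The enrichment sampler does not condition on chromosome or isochore
  composition and allows randomised peaks to overlap, unlike GAT's segment
  algebra; for sparse peaks the difference is negligible but it is not a
  drop-in replacement.
* Training uses plain momentum descent rather than resilient
  backpropagation; with the SSE-improvement stopping rule this is
  deterministic and portable, but absolute accuracies depend on the
  optimiser and should be compared within, not across, implementations.
* The pipeline assumes pre-quality-controlled cells and aligned,
  quantified counts; read processing, peak calling and differential
  binding are out of scope.
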