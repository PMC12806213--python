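# Methods

`pandaml` implements a biomarker-discovery and classification pipeline for
sample-by-feature omics intensity tables (LC-MS metabolomics in particular),
whose core is the PANDA workflow: supervised PLS dimensionality reduction
feeding a feedforward neural network classifier. This note records the
models, the defaults and why, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Preprocessing model

Multi-batch LC-MS feature tables carry technical structure that must be
removed before modelling: irreproducible features, multiplicative batch
effects, right-skewed intensity distributions, and missing cells. The chain
is, in order:

1. **QC filtering.** For each feature, the coefficient of variation
   (CV = sample sd / mean, ddof = 1) is computed over the human-serum QC
   (HSQC) replicate injections *within each batch*, then summarized by the
   mean of available per-batch CVs; batches with fewer than two injections
   contribute no CV. A feature is retained iff its CV statistic is < 0.3
   **and** its mean HSQC intensity is > 1e5, both strict. The per-batch CV
   convention matches the QC-injection design (QC samples interleaved
   within each analytical batch); an alternative reading — CV of per-batch
   HSQC averages — would mostly measure between-batch drift, which the
   normalization step removes anyway.
2. **Batch-wise normalization.** Each feature, within each batch, is
   divided by the batch's HSQC *median* for that feature (falling back to
   the batch median over biological samples if the HSQC median is missing
   or zero). The median is used for robustness to outlier injections. A
   per-ten-sample variant (`mode="per10"`) is available but not the
   default. After this step the per-batch HSQC median of every feature is 1
   wherever defined.
3. **Log + autoscaling.** Natural log, then per-feature standardization to
   mean 0 / sd 1 computed over *biological* samples (ddof = 1). Constant
   features are dropped with a warning rather than divided by zero.
4. **Mean imputation.** Missing cells are replaced by the feature mean over
   observed biological samples. Running imputation last, in transformed
   space, makes the imputed value the feature's transformed mean (≈ 0),
   which is the natural reading of mean imputation per metabolite; running
   it before the log would instead impute the raw-scale mean. Zeros are
   measured values and are never treated as missing.

The whole chain is deterministic; identical inputs give bit-identical
outputs.

## PLS-DA

Class labels are one-hot dummy coded and regressed on column-centered X by
NIPALS PLS2 in regression mode (X and Y both deflated by the X-scores,
unit-norm weight vectors). This is the common PLS-DA convention, so scores,
weights and loadings agree — up to column sign — with other NIPALS codes;
the test suite verifies equivalence to scikit-learn's `PLSRegression`
(`scale=False`) to 1e-8 on random instances. The default is 8 components;
extraction is capped with a warning if a residual matrix degenerates.

Model quality:

- **R²Y** — 1 − SS_res/SS_tot of the dummy matrix reconstructed from the
  retained components, on training data.
- **Q²** — cross-validated 1 − PRESS/SS_tot with stratified 7-fold CV
  (seeded fold assignment; the fold count is a conventional chemometrics
  default, configurable).
- **Permutation test** — labels are permuted `n_perm` times (default 999;
  Q² is the default statistic, R²Y optional) and
  p = (1 + #{perm ≥ observed}) / (n_perm + 1), so the smallest attainable
  p is 1/(n_perm + 1) — with 199 permutations, exactly 0.005.

**Classification** is by Mahalanobis distance in score space: each class
contributes a centroid of its training scores; the covariance is the
pooled within-class score covariance with a ridge term
λ = 1e-6·trace(Σ)/d for invertibility. Distances are computed in the full
retained component space, not the 2-D plotting plane — truncation would
discard information; the 2-D choice is available as an option. Ties break
by class order. Soft class memberships for AUC/loss are
softmax(−d²/2), i.e. equal-prior Gaussian likelihoods under the shared
covariance.

**Confidence regions** for 2-D score clouds use the sample mean and
covariance with squared radius χ²₂(level) (default 0.95 → 5.991). The
small-sample Hotelling (F-based) radius is available via `radius="f"`.

## Neural networks

The classifier is a NumPy multilayer perceptron: z-score input
standardization fit on the training set only, hidden layers of a shared
width, softmax output, categorical cross-entropy plus an optional L1/L2
penalty on weight matrices (never biases). Gradients are hand-derived and
verified against central finite differences to 1e-5 relative error for
every activation/penalty combination. Optimization is mini-batch Adam
(plain SGD optional); `hidden_layers=0` degenerates exactly to multinomial
logistic regression. Training runs a fixed number of epochs (default 100)
with no early stopping; per-epoch train/validation loss and accuracy are
recorded. Everything is deterministic given the config seed.

The hyperparameter search is a plain grid over the axes hidden layers,
layer size, learning rate, activation, regularization (+strength) and batch
size, selecting maximal validation accuracy with ties broken by lower
validation loss then grid order. `default_search_grid()` is the full
factorial {1,3,5}×{10,30,60}×{1e-2,1e-3}×{relu,tanh}×{none,l2}×
{1e-4,1e-2}×{16,32}; the benchmark harness defaults to a compact 4-point
grid because the full grid's cost buys little on the synthetic cohorts —
both are user-overridable.

The autoencoder is symmetric: optional nonlinear hidden layers, a linear
latent layer (conventionally 2–10 dimensional), a mirrored decoder with a
linear output, trained on mean-squared reconstruction error. With zero
hidden layers it is a linear (PCA-like) subspace fit, which is also the
harness default for speed and robustness. The latent dimension is selected
by training a downstream classifier per candidate and taking the best
validation accuracy (ties prefer the smaller dimension).

## Benchmark workflows

Biological samples (QC/blank roles excluded) are split 60:30:10 into
train/validation/test, stratified by class — equivalently a 90:10
modelling/test split whose modelling part is split 60:30; these are the
only fractions under which the two ratios are mutually consistent. The four
workflows on one split:

1. **plsda_classifier** — PLS-DA fit on train+validation combined (the
   score plot is a train+validation construct; only the held-out test set
   is classified), Mahalanobis classification of the test set.
2. **ann_raw** — hyperparameter search on train/validation over all
   features; best model evaluated on test.
3. **ann_autoencoder** — latent dimension selected on validation accuracy,
   autoencoder refit, downstream search + evaluation on codes.
4. **panda** — PLS (8 components) fit on the *training partition only*
   (the stricter no-leakage choice; fitting on train+validation is
   configurable), validation/test projected, search + ANN on scores.

Metrics: argmax accuracy; rank-based (Mann-Whitney, midrank ties) AUC,
macro-averaged one-vs-rest for multiclass; mean categorical cross-entropy.
Cross-validation is repeated Monte-Carlo splitting (default 10 repeats,
split seeds seed+i). Workflow comparisons are paired: every workflow sees
identical partitions per repeat, asserted by hashing the partition.

## Differential and pathway statistics

- **Volcano selection** — per-feature Welch t (unequal variances, the
  robust default for unequal cohort sizes) on log-scale values;
  log2 fold change as the difference of group means; Benjamini-Hochberg
  across features; significant iff q < 0.05 and |log2FC| > log2(1.5).
  The q and fold-change defaults are conventional metabolomics practice
  and configurable.
- **Gene mutation filter** — the strict printed rule for the
  transcriptomic subset: linear fold change < 0.5 AND FDR q < 0.05.
- **Metabolite z-scores** — z = (x − mean_ref)/sd_ref per sample and
  feature against a reference group; summarized as the mean over the
  target group. Zero-sd reference features are skipped with a warning.
- **Stage trends** — "linear trend" is operationalized as OLS of the
  (transformed) feature value on integer-coded ordinal stage (T1–T4 → 0–3,
  N0–N2 → 0–2), two-sided t on the slope, BH across features. One-way
  ANOVA with BH gives the any-difference stage selection.
- **Pathway scores** — directional Stouffer combination Σz/√n of member
  z-scores intersected with the measured universe. A signed, directional
  statistic is required because pathway activity is reported as enrichment
  vs depletion; unsigned over-representation tests cannot express that.
  The two-omics integration scores gene and metabolite layers separately,
  plus a combined score over the union, and flags pathways whose layers
  move in opposite directions (the pattern of interest when transcript and
  metabolite levels diverge) and pathways covered by a single layer.
  Member z-values for integration derive from the feature statistics as
  z = sign(log2FC)·Φ⁻¹(1 − p/2).

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: log-normal
base intensities with feature means spanning 1e4–1e7 (so the 1e5 intensity
filter has bite) and log-sds 0.2–0.6; a configurable number of analytical
batches (default 11) with per-batch, per-feature multiplicative effects
(log-sd 0.3); HSQC/PQC injections per batch drawn around each feature's
grand median with a target replicate CV (default 0.1); blanks near zero;
MCAR missingness (default 2%). Informative features are shifted by
`effect_size`·σ_j on the log scale in the non-reference class(es), with a
random sign per feature; they are drawn from features whose base intensity
clears the QC intensity filter with margin, so injected signal is not
destroyed by the generator's own QC step. Correlated noise blocks share a
latent factor per block — this high-dimensional correlated structure is
what makes PLS compression competitive with a raw-feature ANN. Staged
cohorts add a per-stage log-shift (`stage_slope`) to trend features.
Generators are pure functions of spec + seed.

What passing synthetic tests does **not** show: real LC-MS data have
intensity-dependent missingness, drift within batches, annotation errors
and non-log-normal tails, none of which are simulated; absolute accuracies
on synthetic cohorts say nothing about clinical performance, only that the
pipeline recovers structure it is designed to recover and stays at chance
when none exists.

## Problem sizes and reproducibility

The test suite and the acceptance script run cohorts of 100–200 biological
samples × 240 features, 5–20 Monte-Carlo repeats, 60-epoch network fits on
a compact 2–4 point grid, and 99–199 label permutations; these sizes give
stable estimates for the properties being checked while keeping a full run
in the low minutes on one core. All randomness flows from explicit seeds
(the CLI derives fixed per-stage offsets from one global seed), and the
full simulate → preprocess → benchmark chain is byte-identical under a
fixed seed.

Known limitations: NIPALS component extraction on near-degenerate residuals
caps early rather than attempting re-orthogonalization; Mahalanobis
probabilities assume a shared pooled covariance and equal priors; the
trend screen assumes equally spaced stage codes (a Jonckheere-Terpstra
alternative is a natural extension and is not implemented); mean imputation
shrinks variance and is kept only because it is the convention this
pipeline reproduces.
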