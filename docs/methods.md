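# Methods

## Overview

`lateomics` implements a late-integration multi-omics prediction framework:
each omics layer is preprocessed and feature-selected independently, the
selected blocks are concatenated into one sample × feature matrix, and a
small feed-forward network is fitted on the integrated matrix — a binary
survival-risk classifier on patient-style data, a multi-output IC50
regressor on cell-line-style data. Drug responses are additionally
binarized into sensitive/resistant calls per drug. A synthetic-data module
generates ground-truthed inputs for every stage, so all claims made by the
test suite are about recovery of planted signal, never about real cohorts.

## Preprocessing

Matrices are samples × features with `NaN` for missing. The pipeline order
is fixed: drop samples with more than `max_missing_frac` (default 0.2)
missing values, then drop features by the same rule recomputed on the
surviving samples; impute remaining holes by feature-neighbour kNN (each
missing cell takes the mean of the k = 10 nearest features by
nan-Euclidean distance over co-observed samples, donors restricted to
features observed in that sample — the R `impute.knn` convention, realized
through scikit-learn's `KNNImputer` on the transposed matrix); then scale
(mRNA: per-feature z-score; miRNA: `log2(x+1)` then z-score; protein
RPPA, methylation β, GISTIC2 copy-number and binary mutation layers pass
through as already scaled at source; imputed mutation cells are
re-binarized by rounding). Samples-before-features filter order is a fixed
convention of this package. Cell-line tables additionally require IC50
coverage for at least 80% of drugs before the same filter/impute treatment.

## NCA feature selection (NCFS)

The selector learns a nonnegative per-feature weight vector `w`, the
diagonal specialization of a learned quadratic metric,

    d_w(x_i, x_j) = Σ_l w_l² (x_il − x_jl)²,

and maximizes the expected leave-one-out neighbour agreement

    p_ij = κ(d_w(x_i,x_j)) / Σ_{k≠i} κ(d_w(x_i,x_k)),   κ(z) = exp(−z/σ),
    f(w) = Σ_i Σ_{j: y_j = y_i} p_ij − λ Σ_l w_l²                (classification)
    f(w) = −Σ_i Σ_j p_ij |y_i − y_j| − λ Σ_l w_l²                (regression)

by gradient ascent from `w = 1` with step halving on non-improving steps
(accepted objectives are non-decreasing by construction) and clipping at
zero. The gradient is analytic and evaluated in O(n²p) through matrix
products. The softmax is computed with a per-row shift by the minimum
off-diagonal distance, which is exact by kernel-ratio invariance and keeps
the computation finite for any spread of distances.

Defaults and their rationale:

- `sigma = None` → auto-scaled to the mean off-diagonal pairwise distance
  at the initial weights, frozen for the whole fit. A fixed unit width is
  useless when initial distances grow like 2p (all off-nearest kernels
  underflow and the gradient vanishes); the mean-distance scale keeps the
  softmax informative for any feature count. A fixed σ can still be set.
- `lam = None` → 1/n_samples, the customary NCA-feature-selection default.
- `max_iter = 100`, `tol = 1e-6` relative objective change.
- Selection rules: `top_k(k)` or `weight_above(τ·max weight)` (τ = 0.1
  default); ties always break by ascending feature index.
- The regression loss uses the absolute target difference |y_i − y_j|, the
  natural graded analogue of the same-class indicator.

A known limitation, measured on the synthetic benchmark: at n = 200,
p = 500 with 10 weak planted features, the NCA ranking recovers about
70–80% of the planted set in its top 20, a few points below a univariate
point-biserial ranking on the same data. The LOO-kernel objective can
genuinely favour occasional noise features in the p ≫ n regime; this is a
property of the objective, not of the optimizer (an L-BFGS-B fit of the
same objective lands within noise of the gradient-ascent fit).

## Late integration and clinical covariates

Selected per-layer columns are concatenated in declared layer order and
prefixed by their source; numeric clinical covariates pass through and
categorical ones are one-hot encoded. Clinical covariates bypass feature
selection by design. Three layers of n selected features each yield one
m × 3n matrix.

## SMOTE

Minority samples are oversampled to `round(target_ratio · majority)` by
drawing `x_new = x_i + u (x_nn − x_i)` with `u ~ U(0,1)` and `x_nn` one of
the k = 5 nearest minority neighbours of a random minority sample;
originals are preserved verbatim and first. Balancing is applied to the
integrated matrix before cross-validation splitting. This ordering copies
the upstream workflow it emulates and is a documented leakage caveat:
synthetic points interpolate minority pairs that can straddle future fold
boundaries, so cross-validated metrics on balanced data are optimistic
relative to a fully nested protocol.

## Networks and training

Architectures are tanh hidden layers (defaults: 7+7 classifier, 11+11
regressor) with a two-neuron softmax head (classifier) or one linear
output per drug (regressor). The training objective is

    L(θ) = (1 − γ) · data(θ) + γ · mean(θ²),

with `data` the mean cross-entropy (predicted probabilities clamped at
1e-12) or the mean squared error over observed targets (missing targets
excluded). γ ∈ [0,1] is the regularization ratio; its value is a free
config knob (0.1 classifier / 0.3743 regressor defaults).

Inputs are standardized to the training split's per-column mean/sd, stored
with the fitted network and re-applied on prediction; integrated matrices
mix z-scored and source-scaled columns whose spreads differ several-fold,
which would otherwise distort the shared weight penalty.

Training is full batch. The classifier uses nonlinear conjugate-gradient
rounds (scipy CG with analytic backprop gradients); the regressor uses
Levenberg–Marquardt on the residual vector
`[√((1−γ)/N)·(ŷ−y)_observed ; √(γ/P)·θ]` with an analytic Jacobian
(vectorized backprop per output), falling back to conjugate gradient above
250 parameters where LM's per-iteration factorization dominates; the
training report records which optimizer ran. A standalone fit splits the
samples 70/15/15 into train/validation/test, trains in short rounds, and
stops when the validation loss has not improved for `patience` rounds
(best parameters restored). Fold models inside cross-validation instead
train on the whole training fold for a fixed round budget — the held-out
fold is the validation — because an inner carve-out wastes a third of each
fold and early-stops on noisy handfuls of samples. Everything is
deterministic under a fixed seed.

Hyperparameters (γ, hidden nodes, layer count) can be tuned by Bayesian
optimization: a Matérn-5/2 Gaussian-process surrogate over the unit cube,
Latin-hypercube initial design (all-integer spaces small enough to fit the
design are enumerated outright), expected-improvement acquisition over
random candidates, and the incumbent is the lowest observed
cross-validated loss.

## Drug-response binarization

Per drug, on observed IC50 z-scores (lower = more sensitive):

- **K-means**: the two-cluster within-cluster sum of squares is minimized
  exactly — in one dimension the optimal K=2 partition is a contiguous
  split of the sorted values, found by a prefix-sum scan over all n−1
  splits. The lower-mean cluster is sensitive; the threshold is the
  midpoint between the largest sensitive and smallest resistant value.
- **Waterfall**: values sorted descending form the waterfall curve. If its
  Pearson correlation with the rank index exceeds 0.95 the curve is deemed
  linear and the threshold is the median; otherwise the curve is smoothed
  with a Gaussian filter (sd 3 ranks, reflected boundaries) and the
  threshold is the smoothed value at the index of the largest |second
  difference| (a first-difference mode is switchable). The smoothed value
  is used because on a sharp step the raw value at the inflection index
  hugs one level while the smoothed value interpolates the gap.

Predictions call sensitive strictly below the threshold; ties are
resistant; missing predictions stay missing. Drugs whose cross-validated
binarized-call accuracy falls below 0.5 are dropped before the final
regressor is fitted.

## Synthetic data: what it emulates, and what not

Each layer derives from an independent standard-normal latent matrix mapped
monotonically onto the layer's native scale (identity for expression,
Beta(2,2) quantile transform for methylation β, tanh for copy-number
scores, thresholding against per-gene rates of 5–40% for mutations,
exponential-family counts for miRNA RPM). Outcome scores are linear in the
**standardized native** values of the planted informative columns — i.e.
in exactly what a downstream model can observe — with Gaussian residual
noise: survival labels threshold the noisy score at the analytic quantile
matching the target minority fraction (default 0.3, in the range of
adverse-outcome rates in breast-cancer cohorts and large enough for
planted-signal recovery at n ≈ 200); IC50 columns are per-drug
standardized linear responses, with an optional bimodal subset (±2 shift
by the sign of the linear score) that also produces the step-like sorted
profiles waterfall analysis expects. Missingness is injected completely at
random, which keeps the 20%-filter semantics unambiguous. Default residual
noise sd is 1.0, equal to a single feature's standardized effect.

Not emulated: correlation structure between features (LD, co-expression,
pathway structure), batch effects, informative missingness, raw-scale IC50
dose-response curves, and survival times (risk is binary here). Passing
tests therefore demonstrate that the pipeline recovers linear planted
signal under MCAR missingness — not performance on real TCGA/GDSC cohorts.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's scaled-down study conditions:

- Feature selection benchmark: one layer, n = 200, p = 500, 10 informative
  features of standardized effect 1.0.
- Survival pipeline: n = 300 patients, three layers × 50 features, 5
  informative each at effect 1.5, top-15 NCA selection, SMOTE, 7+7
  classifier, 10-fold cross-validation.
- Drug pipeline: 80 cell lines, four layers × 30 features, 3 informative
  each, 20 drugs (5 bimodal) at effect 1.0, top-5 NCA selection, 11+11
  regressor, 5-fold cross-validation. Fifty cell lines — closer to a real
  single-tissue panel — leave per-drug out-of-fold correlation at the
  noise ceiling even for an oracle ridge fit on the true features, so 80
  is the smallest size at which the planted-signal contract is meaningful.

On synthetic drugs the K-means/waterfall threshold concordance is reported
but low: unimodal standardized columns all have near-zero thresholds under
both methods, so the across-drug correlation is mostly noise — unlike real
panels, where thresholds vary widely across drugs.

## Numerical conventions

- Zero-variance features z-score to all-zeros (logged), and zero
  denominators in ratio metrics yield 0 with a warning.
- "False positive rate" is fp/(fp+tn); the false discovery rate
  fp/(tp+fp) is emitted alongside because published tables sometimes print
  it under the FPR name.
- AUROC is the rank-based (Mann–Whitney) estimator with midranks for ties;
  the "regression value" is the Pearson r between predicted and observed
  values (r² also reported).
- All stochastic components (generators, splits, SMOTE, initializations,
  tuner) take explicit integer seeds; pipeline artifacts are stamped with
  the config hash and seed.
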