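# Methods

## The staging problem

The Alzheimer's continuum is graded clinically as NC → EMCI → LMCI → AD.
The pipeline stages subjects in two phases: (1) select a small subset of
longitudinal cortical-geometry features that track global cognition
(MMSE), and (2) classify subjects into the four stages with a
hierarchical cascade of binary classifiers built on the selected imaging
features and/or baseline clinical covariates.

## Temporally constrained group-sparse regression

### Objective

For T visits, design matrices X_j (n × d) and responses y_j, the solver
minimises over W ∈ R^{d×T}

J(W) = ½ Σ_j ‖y_j − X_j w_j‖² + λ₁‖W‖₂,₁ + λ₂ Σ_{j<T} ‖w_j − w_{j+1}‖₁
     + λ₃ Σ_{j<T} ‖X_j w_j − X_{j+1} w_{j+1}‖².

* λ₁ (default 0.25) controls joint row sparsity: a feature is kept at all
  visits or dropped at all visits.
* λ₂ (default 0.08) is a fused-lasso penalty making each kept feature's
  weight profile piecewise constant over visits.
* λ₃ (default 0.04) penalises changes in the fitted cognitive score
  between adjacent visits.  It requires the same subjects row-aligned at
  every visit (enforced; a misaligned design with λ₃ > 0 is an error).
  Defaults are the study settings, exposed in the run configuration.

Visits are ordinal indices 1..T; no calendar spacing is modelled.

### Optimisation

The data term plus the λ₃ term is a convex quadratic in vec(W) with a
block-tridiagonal Hessian (blocks couple adjacent visits only).  The two
nonsmooth penalties have closed-form proximal maps separately but not
jointly, so the solver uses consensus ADMM with two consensus copies:

* W-update: one Cholesky solve against the cached factor of
  H + 2ρI (refactorised only when ρ changes);
* Z₁-update: row-wise group soft-thresholding (prox of the L2,1 norm);
* Z₂-update: per-row exact 1-D total-variation prox, computed by
  Condat's direct algorithm (written in-package; no installed library
  exposes an exact 1-D TV prox).

The consensus weight ρ is initialised to the mean diagonal of the
per-visit Gram matrices (the curvature scale of the data term — with
ρ ≪ n the W-update all but ignores the consensus copies and the primal
residual stalls) and adapted by residual balancing (×2 / ÷2 when the
primal/dual residual ratio exceeds 10, every 25 iterations, bounded to
six decades around the initial value).

ADMM is not monotone in the objective, so the reported
`objective_trace` records the best objective seen so far, evaluated at
the group-sparse consensus copy Z₁; `W_hat` is the iterate attaining it.
Using Z₁ (rather than W) gives exact zero rows, which is what feature
selection consumes.  Convergence is declared when the relative decrease
of the best objective stays below `tol` (default 1e-8) for 10
consecutive iterations and both consensus residuals are below 1e-7 of
the iterate scale; otherwise the solve stops at `max_iter` (default
5000) with `converged=False` — a report, not an exception.

On random small instances the solver's objective agrees with an
independent smoothed-surrogate minimiser (epsilon-continuation L-BFGS-B)
to better than 1e-6 relative; with λ₂ = λ₃ = 0 and λ₁ at or above the
subgradient threshold max_rows ‖(X_jᵀy_j)_row‖₂ it returns exactly W = 0.

### Standardisation

`fit()` solves the objective on the design as given.  The high-level
selection pipeline (`select_imaging_features`, CLI `select`) z-scores
feature columns and centres responses per visit before fitting, because
the penalties are scale-sensitive; weights are reported on the
standardised scale.  The split keeps the solver's algebraic contracts
(e.g. the unpenalised limit equals per-visit least squares on the raw
system) testable while real-data use gets sensible scaling.

## Importance ranking

Per-visit weights of a selected feature are collapsed by the arithmetic
mean to one signed w — the simplest sign-preserving aggregation; the
published tables print a single signed weight per feature without
stating the rule, so the mean is a declared design choice.  Importance
is |ln|w|| and rank 1 is the largest importance, ties broken
lexicographically on feature id.  Note the direction: all surviving
weights have |w| < 1, where |ln|w|| is *decreasing* in |w|, so rank 1 is
the smallest-magnitude surviving weight.  The package follows that
published convention literally rather than rationalising it.  The
packaged reference table stores printed values; because printed weights
carry 3–4 significant digits, recomputing the log from them can differ
from the printed importance by up to ~2e-3, which consistency checks
allow for.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with ground
truth for recovery experiments:

* features: iid standard normal per column and visit — a neutral choice
  that keeps the regression well-conditioned and matches the z-scored
  scale morphometry is analysed on;
* true weights: s active rows (default 40, the published selection
  size), base amplitude ±Uniform(0.5, 1.5)/√s so the imaging signal in
  the response has SD ≈ 1 regardless of s, per-visit random-walk steps
  bounded by `drift` (default 0.05);
* responses: y_j = X_j w_j + class offset + N(0, noise_sd²), clipped to
  the MMSE instrument range [0, 30].  Class offsets default to the
  class-mean MMSE of the clinical profile, giving the NC > EMCI > LMCI
  > AD ordering.  `noise_sd` defaults to 1.5 — mid-range of the
  published within-class MMSE SDs (1.0–4.5);
* clinical covariates: class-conditional normals (age, education, CDR,
  FAQ, MMSE) and Bernoullis (male sex, married, APOE ε4), with the
  published development- and validation-cohort summaries shipped as the
  `adni_like` presets (class sizes 314/208/258/205 and 417/110/83/75);
* missingness: missing-completely-at-random masking of clinical cells
  at a configurable rate (labels never masked).  MCAR is the only
  mechanism modelled.

What the generator does **not** emulate: spatial correlation between
neighbouring cortical structures, within-subject feature autocorrelation
across visits, class-dependent feature shifts (the class signal enters
through the response and the clinical covariates, not the imaging
features), informative missingness, and diagnostic drift (diagnoses are
stable by construction, matching the emulated cohorts' inclusion
criteria).  Passing tests therefore certify the pipeline's mechanics and
contracts on data with the assumed statistical shape, not clinical
performance on real ADNI scans.

### Support-recovery experiment

The recovery study runs at d = 100 features (s = 10 active), T = 4
visits, 200 subjects, noise_sd = 0.5, drift = 0.05.  Two design choices:

* equal mid-scale class offsets (15) rather than the ADNI-like ones —
  between-class response variance is structured noise unrelated to the
  features (SD ≈ 3 against a unit-SD signal) and would make recovery
  impossible for any method; a recovery study isolates the signal whose
  recovery it measures;
* the penalty level is placed on the regularisation path relative to
  the instance: λ₁ = 0.25 · λ_max of the standardised design (λ_max is
  the smallest λ₁ that zeroes everything), with λ₂, λ₃ scaled to keep
  the 0.25 : 0.08 : 0.04 ratio of the study defaults.  Fixed absolute
  penalties are meaningless across instances of different scale.

Across 20 seeds this yields mean F1 = 0.987 (min 0.889) between
selected and true supports; the tests pin mean ≥ 0.95 and min ≥ 0.85.

## SMOTE

Each synthetic minority sample is x_i + u·(x_nn − x_i) with
u ~ Uniform[0, 1] and x_nn one of the k = 10 nearest minority
neighbours of x_i (Euclidean metric; the pipeline applies it to z-scored
features so the metric is scale-free).  Majority points never
participate, so synthetic samples stay inside the minority convex hull.
Balancing equalises the minority count to the majority count; originals
are preserved verbatim and synthetic rows are flagged.  Binary clinical
columns are interpolated then snapped to the nearest valid code, since
plain SMOTE is defined on continuous spaces.  No variants (borderline
SMOTE, ADASYN) and no undersampling.

## Hierarchical cascade

A scenario is a permutation of the four labels; classifier i separates
order[i] from the union of the remaining labels, and survivors of all
three classifiers receive order[3].  The published list of four
scenarios repeats one ordering, so three distinct presets ship
(NC-EMCI-LMCI-AD, AD-LMCI-NC-EMCI, AD-NC-EMCI-LMCI) and any permutation
string is accepted.

Preprocessing is fitted strictly on training data: FCS multiple
imputation (scikit-learn IterativeImputer, m = 5 chains of 10 cycles
with stochastic draws, collapsed by mean for continuous and mode for
binary columns), then z-scoring, then per-task SMOTE.  Base learners
come from scikit-learn behind a registry; the decision threshold is 0.5
on the peel-class probability (the sources are silent on thresholds).
Hyperparameters default to library defaults; an optional `param_grid`
runs a 3-fold grid search inside the training data for study-style
tuning.  Random-forest (and other tree-ensemble) feature importances
are surfaced per task from the fitted learners; |coef| serves for
linear models.

## Evaluation

Metrics follow the standard confusion-matrix formulas; balanced
accuracy is (SEN+SPE)/2 and AUC uses the Mann–Whitney formulation with
half credit for ties.  Undefined metrics (empty class) are NaN and
named, never silently zero.  Cross-validation is stratified on the
four-class label; pooled metrics are computed from summed out-of-fold
confusion counts and pooled peel scores (micro pooling — well-defined
for F1, unlike averaging fold metrics).  Per-task cascade metrics use
the survivor convention: each classifier is scored on the subjects that
reach it, with its peel class positive.  Temporal validation fits once
on the development table and evaluates untouched on the validation
table.  Rounding is half-up to 3 decimals, applied only at report time;
reported rows are rebuilt from stored counts, never from re-rounded
metrics.

## Numerical and scale choices

* Test and example problem sizes (d ≤ 100 features, cohorts of 60–1,670
  subjects) are chosen so the full suite exercises every contract —
  including the 20-seed recovery study and 10-fold CV — at desk scale;
  the mechanics are size-independent.
* Selection threshold ε = 1e-8 on row norms; the group prox produces
  exact zeros, so ε only guards float noise.
* CSVs are written with `%.17g` and read with round-trip float parsing,
  so all three schemas round-trip to full precision.
* Config hashing: sha256 over canonical JSON of the run configuration.

## Known limitations

* The published headline results (overall accuracy 0.877, the full
  per-task panels) were computed on access-controlled ADNI data and are
  not reproducible here; the package reproduces everything that printed
  numbers fully determine and validates the rest by property.
* The aggregation rule behind the published single-w column is unstated;
  the mean is a declared choice, and ranking depends on it.
* FCS imputation treats binary columns as continuous during chaining
  (rounded afterwards); a fully categorical chained model is out of
  scope.
* The cascade assigns hard labels; no probability calibration or
  ordinal-regression alternative is provided.
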