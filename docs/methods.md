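# Methods

This note records the statistical model behind `metabostage`, the
defaults it ships with, the design of the synthetic cohort generator,
and the numerical choices that matter for reproducing its results.

## Problem setting

The package analyses targeted plasma-metabolomics data from patients in
three ordered coronary-artery-disease stages — stable angina (SCAD),
unstable angina (UA) and acute myocardial infarction (MI) — with the
goal of (i) organising metabolites into co-abundance modules related to
clinical severity and (ii) building diagnostic models that discriminate
adjacent stages better than conventional risk factors alone.  Analyses
operate on two adjacent-stage contrasts, UA vs SCAD and MI vs UA.

## Preprocessing

The pipeline is fixed in order: **filter → impute → QC-RLSC → pareto**.

1. **QC missing-rate filter.** A feature is removed when its intensity
   is zero (or missing) in more than half of the pooled-QC injections;
   surviving zeros are recoded as explicit missing values.  The
   threshold (0.5) is configurable.
2. **Minimum imputation.** Each missing cell is replaced by the
   feature's observed minimum — the conventional
   below-detection-limit convention for targeted panels.
3. **QC-RLSC.** Per feature and per analytical batch, a robust LOESS
   curve (local linear, three robustness iterations, span 0.75 by
   default) is fitted to the pooled-QC intensities against injection
   order, linearly interpolated to every injection, and divided out:
   `corrected = raw × median(QC) / trend`.  Beyond the first/last QC
   injection the trend is extended as a constant (nearest fitted
   value).  A trend that dips non-positive triggers a warning and a
   flat batch-median fallback for that feature.  Batches are corrected
   independently, so between-batch level offsets are deliberately not
   removed here.  At least three QC injections per batch are required.
4. **Pareto scaling.** Study-sample rows are mean-centred and divided
   by the square root of the feature standard deviation.  QC rows are
   dropped at this point; downstream models see study samples only.

## Network analysis

An unsigned weighted network is built from Pearson correlations,
`a_ij = |cor(i,j)|^β` with soft power β = 4 (a soft-threshold scan
reporting the signed scale-free fit index and connectivity is provided
for choosing β on other data).  The topological overlap matrix is

```
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

with `k` the off-diagonal connectivity.  Modules are found by
average-linkage hierarchical clustering of `1 − TOM`, cut at a fixed
height of 0.99 × the maximum merge height — the classic static cut.
(A cut at the 0.99 *quantile* of merge heights was tried first and
rejected: TOM merge heights bunch near 1, so the quantile lands above
the between-module join and collapses everything into one module; the
static fraction-of-maximum cut recovers planted modules exactly.)
Clusters below the minimum size (5) fall into the unassigned "grey"
pool; modules whose eigenmetabolites correlate above 0.9 are merged.
Module labels are deterministic, ranked by size (M1, M2, …) with the
conventional colour names available as aliases.

Each module is summarised by its **eigenmetabolite** — the first
principal component of its standardised member features, unit-norm and
sign-oriented so the average member correlation is non-negative.
Eigenmetabolites are related to clinical severity traits by Spearman
correlation with Benjamini–Hochberg FDR across the whole module ×
trait grid, compared across stages by two-sided Wilcoxon rank-sum
tests, and mined for hub metabolites by intramodular connectivity.

## Association scans

Each metabolite is tested one at a time by logistic regression of a
stage contrast on the scaled feature plus eight fixed covariates (age,
sex, hypertension, diabetes, smoking, LDL-C, HDL-C, TG), complete-case.
The solver is a Newton/IRLS iteration with step-halving, converged when
the largest score component falls below 1e-8; Wald standard errors come
from the inverse observed information.  Quasi-complete separation
(diverging coefficients) and rank-deficient designs are flagged and
reported as missing inference rather than raised.  BH FDR is reported
across the scan; downstream selection gates on nominal p < 0.05.
Linear scans against numeric severity traits use OLS with t inference;
heavily right-skewed markers (hs-CRP, cTnI) are natural-log transformed
by default.

## Diagnostic model building

* **Traditional model** — bidirectional stepwise selection minimising
  AIC over the conventional risk-factor pool (the eight covariates plus
  ApoA, Lp(a), LVEF), run on every training partition of 10 repeats of
  5-fold cross-validation; variables selected in more than half of the
  partitions are refitted by plain maximum likelihood.
* **Metabolic model** — L1-penalised logistic regression over the
  nominally significant metabolites.  Each of 200 iterations draws a
  fresh stratified 5-fold split, traces the cross-validated binomial
  deviance over a shared log-spaced penalty grid, picks the penalty by
  the one-standard-error rule, and records the support of the full-data
  fit at that penalty.  Features kept in more than 100 of the 200
  iterations form the model, refit unpenalised.
* **Combined model** — the same stability selection over the union of
  significant metabolites and standardized risk factors, so both
  predictor families compete under one penalty.

The LASSO path solver is a glmnet-style coordinate descent (IRLS outer
loop, cyclic soft-thresholding inner loop with an active set, warm
starts along the grid, unpenalised intercept), compiled with numba.
`λ_max = max_j |x_jᵀ(y − ȳ)|/n` and the default grid is 100 log-spaced
values down to `λ_max × 1e-4`.  Two numerical choices matter:

* the automatic grid stops early once the fit explains ≥ 98% of the
  null deviance, because on strongly separable data the remaining
  penalties only inflate a saturated fit at large cost while the
  CV-chosen 1-se penalty always lies far above the stop;
* cross-validation fold fits on an explicit grid hold the saturated
  solution constant past that point instead of truncating, keeping the
  deviance curves aligned across folds.

The solver was verified during development against an independent
accelerated proximal-gradient implementation (and agrees to ≤ 1e-8
with reference coordinate-descent software); the proximal-gradient
oracle ships in the test suite.

Final models are plain logistic refits that store their training
standardization, so raw inputs are scored consistently:
`p = 1 / (1 + exp(−(intercept + Σ coef·x)))`, overflow-safe.

## Evaluation

Discrimination is the C-statistic (ties counted half) with a DeLong
structural-components 95% CI.  Model pairs are compared by the
continuous (category-free) net reclassification improvement — exact
probability ties move neither way — and the integrated discrimination
improvement, both with 2000-replicate bootstrap percentile intervals
and normal-approximation p-values; degenerate single-class resamples
are redrawn once.  Group separation of a score uses two-sided Wilcoxon
rank-sum tests.

## Synthetic cohort generator

Real patient-level cohorts of this kind are rarely public, so the
package ships a generator whose defaults define its study conditions.
On the log scale, for feature *j* in sample *i*:

```
z_ij = r_j f_{m(j),i} + δ_j(stage_i) + γ_j(covariates_i) + √(1−r_j²) ε_ij
abundance_ij = exp(base_j + s_j z_ij) × drift(t_i) × tech_ij
```

with independent standard-normal module factors `f`, member loading
r = 0.8 (pairwise within-module correlation r² = 0.64), stage shifts of
0.35 biological SD per adjacent-stage transition planted on 15 module
features, smooth exponential-spline injection-order drift (amplitude
0.15), and multiplicative lognormal technical noise (CV 8%) shared by
study and QC injections.  QC injections are a pooled mean of all true
study abundances, inserted before every block of ten study samples.
Stage membership is confounded with age, sex and HDL-C through a
multinomial logit, reconciled with exact per-stage counts by weighted
sampling without replacement.  Severity traits (SYNTAX, SYNTAX II,
hs-CRP, cTnI, LVMI, stenosed-vessel count) are linear in the latent
factors with stage-dependent offsets, so module–trait correlations have
a planted truth.

The stage-effect default deserves a note: stronger settings (e.g. 0.6
SD on 20 correlated features) produce complete separation of the
stages — combined-model AUC of exactly 1.0 — which no real staging
cohort shows.  The shipped default yields a combined-model AUC in the
low 0.9s against ~0.73 for risk factors alone: an idealised but not
degenerate mirror of the discrimination gain the method is meant to
detect.  Known limits: lognormal abundances with a single shared
latent factor per module (no nested or overlapping modules), drift
shared across features within a batch, missingness purely
intensity-dependent, and covariates drawn independently apart from the
planted stage confounding.

## Problem sizes

The shipped benchmarks are sized for a single CPU core: oracle checks
on ≤ 500 samples × ≤ 50 features; a 400-injection drift-correction
run; module recovery at 300 samples with 8 planted modules;
stability-selection recovery at n = 600 with 63 candidates × 200
iterations; scan calibration over 2000 replicates at n = 250; and an
end-to-end cohort of 310 patients × 120 features.  These sizes are the
package's own choices — large enough that the statistical claims are
sharp, small enough to run routinely.
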