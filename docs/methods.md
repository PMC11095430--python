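# Methods

`clarc` implements an analysis suite for longitudinal amyloid-PET cohorts
quantified on the Centiloid (CL) scale. This note describes the models and
procedures, the choices that were genuinely open, and what the synthetic
cohort generator does and does not emulate.

## The scientific problem

Amyloid-β plaques accumulate for decades before dementia onset. Longitudinal
PET lets one measure each person's **annualized rate of change (ARC)**,

ARC = (CL at last follow-up − CL at baseline) / Δt  [CL/year],

but any observed increase mixes true accumulation with test–retest noise. The
suite answers three questions:

1. **How large must an ARC be to count as reliable accumulation?**
2. **Which baseline CL value best predicts who will accumulate?**
3. **How do CL trajectories depend on group membership and risk factors?**

## Reliable accumulation

Two estimators, both exposed as sklearn-style `fit`/`predict` classes:

**Normative percentile** (`NormativeThreshold`). A *reference group* of
subjects confidently not accumulating is selected: baseline CL < 12 (strict
inequality), all visual reads (VR) negative, CSF amyloid and p-tau flagged
normal. Subjects missing a required flag are never placed in the reference
group. The threshold is the empirical 95th percentile of the reference ARCs,
using the linear-interpolation quantile h = (n−1)p so the number is
reproducible across software. The 95% CI is a subject-level bootstrap
(default 1000 resamples) of that quantile. Classification is strict:
accumulator ⇔ ARC > threshold.

Two readings of the percentile rule circulate: the percentile of *individual*
ARCs (default here, `method="percentile"`) and the upper bound of the 95% CI
of the *mean* ARC (`method="ci_mean"`, mean + z·sd/√n). They differ by a
factor ≈ √n in spread; the individual-level reading is the default because
it is the one that describes single-subject measurement variability.

**Gaussian mixture** (`GaussianMixtureThreshold`). A two-component univariate
Gaussian mixture is fitted to the whole cohort's ARCs by EM (authored here;
cross-checked against scikit-learn's implementation in the test suite). The
threshold is the 99th percentile of the lower-mean component,
μ₁ + z₀.₉₉·σ₁. EM details: best of 10 initializations with means placed at
randomized spread quantiles (fixed sub-seeds), tolerance 1e-8 on the
log-likelihood, at most 500 iterations, per-iteration log-likelihood recorded
(and non-decreasing, an EM guarantee asserted in tests). Component SDs are
floored at 1e-4 × data SD; in addition, solutions in which a component has
collapsed onto a handful of points (weight below max(1%, 2/n) or SD at the
floor) are rejected during model selection, because their likelihood spikes
are not admissible mixture solutions. **Limitation:** on weakly bimodal ARC
distributions (such as the default synthetic world, where slopes vary
continuously with baseline CL) the two components are poorly identified and
the resulting threshold is unstable; the method is reliable only when the
accumulator mode is well separated.

## Baseline-CL threshold prediction

Candidate thresholds are the sorted unique baseline CL values; a subject is
predicted to be a future accumulator iff baseline CL ≥ t (inclusive).
Precision–recall analysis is used rather than ROC because accumulators are
the minority class. For each candidate the exact confusion counts, precision,
recall, specificity and F1 (defined as 0 when precision + recall = 0) are
computed. The optimum maximizes F1, optionally under a minimum-precision,
minimum-recall or minimum-specificity constraint; ties break to the
*smallest* threshold (favoring sensitivity for early intervention).

Bootstrap protocol (`PrecisionRecallThreshold`):

* **Point estimate** — 500 subject-level resamples; the per-resample optima
  are averaged (arithmetic mean; median available). Single-class resamples
  are skipped; if a constraint is infeasible in more than half the resamples
  the run errors with the feasibility rate.
* **95% CI** — 1000 further resamples; each in-bag optimum is recorded and
  validated on its out-of-bag subjects (the out-of-bag F1 is kept as a
  diagnostic); the CI is the 2.5th/97.5th percentile of the 1000 thresholds.
  The "out-of-sample validation" wording this mirrors is underspecified in
  the literature; out-of-bag evaluation per resample is this package's
  interpretation.

Stratified runs (baseline-VR-negative subset, tracer, APOE-ε4 carriership,
education tier) repeat the procedure per stratum with deterministic
per-stratum sub-seeds; strata lacking one of the two classes are reported as
not estimable rather than raising.

## Longitudinal trajectories

The base linear mixed-effects model is

CL ~ time + group + group×time + (random intercept and slope | subject),

with an unstructured random-effect covariance. The reference group is
allowed a random intercept only: its random-slope design column is zeroed in
a single joint fit (a slope-variance mask), rather than fitting two separate
models. Baseline age enters centred at 65 years.

Covariates are tested in a fixed order — baseline age, APOE-ε4 carriership,
tracer, sex, education — each retained iff it lowers AICc
(−2ℓ + 2k + 2k(k+1)/(n−k−1), k counting fixed effects, covariance parameters
and the residual variance) *and* its |t| exceeds the normal critical value at
α = 0.05 (normal approximation throughout; no Satterthwaite). The ×time
interaction of each candidate is tested separately on top of the main
effect, and the main effect is kept whenever its interaction is retained
(hierarchy). Every comparison (AICc before/after, t, p, decision) is recorded
in an audit trail. Model comparisons use maximum likelihood; final reported
estimates use REML.

Confidence intervals come from a **cluster bootstrap**: whole subjects, with
all their scans, are resampled with replacement (default 1000 draws) and the
model refit; percentile CIs are taken per term. Refits that fail or lose a
factor level are skipped and counted; more than 10% failures is an error.

VR-category and cognition analyses reuse the same machinery with
VR-over-time (stable VR−, converter, stable VR+) or CDR-based cognitive
status as factors; VR+→VR− reverters are excluded from those factors.

### Numerical core

The fitting machinery is a profiled-likelihood solver written for this
package's structure (hundreds of subjects, 2–3 scans each, two random
effects): the scaled random-effect covariance is parametrized by its
log-Cholesky factor, the fixed effects and residual variance are profiled
out in closed form, and per-group operations are batched over equal-sized
groups. It reaches the same ML/REML optimum as statsmodels `MixedLM`
(asserted to 1e-3 in log-likelihood and 1e-4 in coefficients in the test
suite) roughly two orders of magnitude faster, which is what makes
subject-level bootstrap CIs affordable on one CPU. Residual variance is
floored at 1e-10 so noise-free (degenerate) inputs remain fittable; the
covariance optimization uses Nelder–Mead from moment-based starting values
(per-subject OLS of residuals), warm-started during bootstrap loops.

## Synthetic cohort generator

`SimConfig`/`generate` produce a cohort with the statistical structure the
analysis assumes, standing in for restricted multi-centre data, plus a truth
table (latent baseline CL and true slope per subject) for recovery tests.

Stated world (defaults):

* **n = 750** subjects; 64% flutemetamol (FMM), 36% florbetaben (FBB).
* **Age** ~ Normal(65.7, 7.6²) truncated at 50; 57% female; APOE-ε4 allele
  counts (0/1/2) with probabilities 0.58/0.37/0.05 (2% missing); education
  tiers 18%/29%/53%; CDR 0.5 in 6%.
* **Baseline CL** — mixture of Normal(2.4, 5.7²) (weight 0.579, the stable
  near-zero population) and 10 + LogNormal(2.4057, 1.0952²) (weight 0.421,
  the pathological right tail). The three mixture parameters solve the
  moment equations for population mean 14.1 CL, SD 24.6 CL and 17.5% of
  latent baselines above the visual-read threshold.
* **Trajectories** — CL_true(t) = CL0 + slope·t with
  slope = a₀ + a₁·CL0 + a₂·CL0² + covariate effects + Normal(0, 1.5²);
  default quadratic (0, 0.15, −0.00125) peaks near 4.5 CL/yr at 60 CL. The
  between-subject slope SD of 1.5 CL/yr makes the reference-group ARC spread
  (1.5 between-subject plus ≈0.9 propagated measurement noise) land at the
  ≈3 CL/yr scale reported for reliable accumulation, and the overall ARC SD
  at ≈3 CL/yr.
* **Measurement** — observed CL = latent + Normal(0, 2.0²) per scan (the
  2.0 CL test–retest SD is an assumption, exposed in config); FMM scans read
  5 CL higher than FBB (a calibration offset applied to observed values
  only, mean-centred so population moments are preserved).
* **Visual reads** — per scan, VR+ ⇔ latent CL > 24, XOR a 2% symmetric
  reader error. 24 CL sits in the published 17–26 CL range of VR-derived
  thresholds and is the value consistent with 18% baseline VR+ alongside the
  baseline-CL moments; the 2% flip reproduces the observed ≈1.6% rate of
  VR+→VR− reverters.
* **Schedule** — one follow-up (87%) or two (13%); intervals lognormal with
  medians 3.0 and 5.3 years.
* **CSF** — P(normal flag) = logistic((15 − CL0)/5) for amyloid and p-tau
  independently; flags jointly missing with probability 0.5 (without
  missingness the reference group would be ~3× the realistic size). The CSF
  model is synthetic-only and not calibrated to any assay.

Not emulated: scanner/site effects, SUVr kinetics, tracer-specific follow-up
schedules (in the real data three-timepoint subjects are all FBB), cognitive
decline, non-linear latent trajectories, informative dropout. A green
recovery test therefore establishes correctness of the estimators under the
stated generative model, not robustness to these real-world features.

## Degenerate inputs and tie-breaks

* ARC: subjects with one scan or zero follow-up interval are excluded with a
  log message. `rule="max_cl"` uses the highest-CL follow-up (and its own
  Δt) instead of the latest.
* A VR sequence −,+,− is classified as a converter (first conversion wins);
  the alternative reading is noted but not asserted.
* Accumulator rule is strict (>) at the ARC threshold; prediction rule is
  inclusive (≥) at the baseline-CL threshold.
* Normative threshold on constant input returns that constant with a
  zero-width CI; fewer than 2 values is an error, fewer than 20 a warning.
* GMM on zero-variance input raises; an unconverged fit must be forced.

## Scaling in the test suite

The acceptance-style simulation tests scale the published bootstrap sizes
down to run on one CPU: 400-subject cohorts with 100 bootstrap draws per CI
for the mixed-model recovery check, and 650-subject cohorts with the full
500/1000 resampling protocol for the threshold-recovery check. Library
defaults keep the full sizes.
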