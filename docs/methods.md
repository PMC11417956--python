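# Methods

## The validation problem

A bone-resorption marker measurable in urine is useful for growth studies
only if (i) its biological variability is characterized (day-to-day CV,
diurnal pattern), and (ii) its age trajectory tracks an independent
measure of skeletal growth. This package implements that validation as a
pipeline: preprocessing of raw urine and forearm tables, descriptive
variability statistics, one Bayesian regression per outcome, and a rank
correlation between the two models' age-smooth estimates, per sex.

## Preprocessing

* **SG correction.** `ctx_sg = ctx_raw · (SG_ref − 1)/(SG_sample − 1)`,
  exact under pure water dilution. The reference SG defaults to the mean
  SG of retained samples (configurable; refractometry protocols vary in
  their reference value). Samples with
  SG < 1.003 are discarded before correction; the boundary value 1.003
  is retained (the discard rule is strictly `<`).
* **Velocities.** For consecutive length measurements,
  `fgv = (L2 − L1)/Δdays`, anchored at the midpoint "velocity date";
  age = (velocity date − birthdate)/365.25. Measurement noise makes a
  minority of velocities slightly negative; they are clamped to half the
  smallest positive observed velocity (configurable; absolute fallback
  1e-6 cm/day if no positive value exists). Clamping preserves the order
  of positive values and keeps the log transform finite. The clamp is this
  package's choice among the possible positivity transforms (shift,
  absolute value, clamp); it is the only one that leaves positive
  values untouched.
* **Standardization.** Predictors are centered and scaled to two sample
  standard deviations (so a binary and a continuous predictor move the
  response on comparable scales). Age uses the gradient pooled across
  both datasets — both models share one age scale — while sex (0/1 male
  indicator) is standardized on the pooled data and time of day within
  the urine dataset. Responses are log-transformed but not standardized.

## The regression model

Skew-normal likelihood in the mean parametrization: `mu` is the mean,
`sigma` the SD, `alpha` the shape; internally converted to the direct
(location/scale/shape) parameters, with `alpha = 0` reducing exactly to
the normal. Only `mu` carries covariates; `sigma` and `alpha` are scalar
free parameters (identity links). The mean structure is an intercept, a
9-coefficient age smooth, 9 male-deviation smooth coefficients, a sex
main effect, a time-of-day effect (CTX model only), and random
intercepts per individual and site plus a random age slope per
individual (non-centered, independent — no correlation parameter, a
deliberate minimal choice exposed in the model spec).

**Spline basis.** Cubic B-splines of basis dimension 10 ("ten knots" in
the field's loose usage), interior knots at equally spaced quantiles of
standardized age. The raw basis is a partition of unity, hence collinear
with the intercept; identifiability comes from centering each column and
dropping the final (oldest-age) column, which is the negative sum of the
centered others, leaving 9 coefficients at full rank. Each coefficient is
a local bump labeled by the age window holding most of its mass
(0–2.5, 2.5–4.5, 4.5–7, 7–9, 9–11, 11–13, 13–15, 15–17.5, 17.5–20
years). Because the female curve is the reference, a fitted coefficient
is interpretable as the female curve's local level relative to the
oldest-age reference bump, and the male deviation adds to it. Raw
(unpenalized) coefficients are used rather than a penalized smooth
because per-window estimates with intervals are the quantity of
interest.

**Priors.** Coefficient priors are zero-centered normals with scale
expressed in units of the response SD (default 1 response-SD). The
male-deviation coefficients whose windows overlap 5–11 years — where the
sexes are expected to differ, females having the earlier, shorter growth
spurt — get informative priors: scale 0.5 response-SD in the velocity
model (doubled, i.e. less informative, in the CTX model) and centers
−0.5 response-SD (windows ending by age 9) or +0.5 (the 9–11 window,
where only males are still mid-spurt). Scale parameters (`sigma` and the
three random-effect SDs) get half-normal(1) priors; `alpha` a
normal(0, 5). These prior constants are declared
defaults, configurable in `ModelSpec`.

**Sampling.** An in-package No-U-Turn Sampler: slice-variant tree
doubling, dual-averaging step size toward a target acceptance
(adapt-delta 0.99 at the default full-scale settings of 5 chains ×
10,000 iterations with 2,000 warmup; desk and test runs use 2 × 1,500
at 0.9), diagonal mass matrix re-estimated twice during warmup,
divergence flagged at an energy error of 1000. Gradients of the joint
log posterior are analytic, including the skew-normal derivatives in the
mean parametrization (verified against finite differences). A
gradient-free adaptive random-walk Metropolis (target acceptance 0.234,
5× iterations) is provided as a fallback. Chains are initialized at a
ridge least-squares solution with per-chain jitter; a non-finite initial
density raises immediately with diagnostics.

**Diagnostics.** Split-chain Gelman–Rubin R-hat in the conservative form
`sqrt((W + B/h)/W)` (always ≥ 1, exactly 1 when all split halves share a
mean); effective sample size via Geyer initial-positive-sequence
truncation of chain-averaged autocorrelations; posterior predictive
checks comparing mean, SD, skewness, min and max of observed data
against replicated datasets (tail probabilities outside [0.05, 0.95]
flag misfit). A fit warns — never silently succeeds — when all R-hat
exceed 1.1.

## Sex-specific tables and the headline correlation

Per model, the nine main-smooth coefficients (posterior mean and central
95% interval) form the female row; the nine deviation coefficients the
difference row; male rows are derived two ways, both emitted: the
verbatim additive rule (summing estimates *and* interval bounds, a
convention some published tables use) and a proper posterior-sum interval
(quantiles of summed draws). Posterior means of sums add exactly, so the
two derivations agree on estimates and differ only in bounds — adding
interval endpoints is not a valid interval and is kept for replication
only.

Spearman correlation uses average ranks for ties; the p-value is the
exact permutation distribution when n ≤ 9 without ties (all 9! = 362,880
orderings enumerated) and the t approximation with n − 2 degrees of
freedom otherwise. The printed female estimate columns give
rho = 0.833, exact p = 0.0083.

## The synthetic cohort generator

The generator is the study's stand-in for the deposited data: 81
individuals (sex ratio 0.46 female) across 11 sites, 364 forearm
measurements (1–10 per individual, ≥ 90 days apart), 187 urine samples
from a 48-individual subset (1–18 per individual, collection times
uniform over 07:00–18:00), ages 0–20 years.

* **Velocity curves.** A Gaussian spurt bump (optionally mixed with a
  birth plateau) times a quadratic taper that reaches exactly zero at
  the cessation age. Female default: peak 5.5 y, width 2.2 y, height
  0.012 cm/day, cessation 18 y (realized argmax ≈ 4.8 y). Male: peak
  7 y, width 2.5 y, height 0.0095, cessation 20 y, plateau 0.3
  (high velocity from birth, realized argmax ≈ 5.7 y). Forearm length
  is the quadrature integral of the curve from birth (birth length
  22 cm) scaled by a per-individual lognormal growth factor, plus
  Gaussian measurement error (SD 0.05 cm) — which yields the observed
  small negative velocities at near-cessation ages.
* **CTX curves.** Gamma-type bump (peak 4 y) plus a linear post-10-year
  log decline. The female curve is coupled to the velocity curve:
  log CTX follows `log(velocity + floor)` — floor 5% of peak velocity,
  representing the baseline whole-skeleton remodeling that persists
  after long-bone growth stops — standardized and scaled to the female
  CTX amplitude (1.2 log units), a strictly monotone image of velocity.
  The male curve is uncoupled and deliberately weak in age structure
  (amplitude 0.12, decline 0.015/y): with both male curves constrained
  to decline after age 10, a male velocity/CTX *rank* decorrelation is
  only possible when the male CTX age signal is small relative to
  biological noise, and that weak-structure condition is what "the
  biomarker does not track male growth" means operationally. The cost is
  that the synthetic male CTX decline is shallower than a real cohort's.
* **Noise.** The day-to-day CV target maps to a total log-scale variance
  `log(1 + CV²)`, split 60/40 between a per-(individual, day) lognormal
  day effect and a skew-normal within-day residual (shape −4, matching
  left-skewed log outcomes), so repeated same-time sampling realizes the
  CV target by construction. Individual (SD 0.30) and site (SD 0.10)
  log-intercepts add between-individual structure. The diurnal effect is
  linear in minutes on the log scale, referenced to 07:00, with slope
  `log(0.55)/660` per minute targeting a 0.55 evening/morning ratio.
  Specific gravity is truncated normal (mean 1.013, SD 0.006, ≥ 1.0005),
  putting a few samples per cohort below the 1.003 QC threshold.

What the generator does **not** emulate: menstrual-cycle, dietary and
activity influences on CTX-I; assay-level error structure (duplicate
CVs, plate effects); non-uniform sampling-time distributions; real
pedigree/site confounding. Passing tests therefore demonstrate that the
pipeline recovers known structure of this statistical form at study
scale — not that a real cohort of this size would yield equally clean
results.

## Problem sizes and numerical choices

Reduced sampler settings (2 chains × 1,500 iterations, 500 warmup,
adapt-delta 0.9, tree depth ≤ 8) are used for desk runs, tests and the
recovery studies; they converge cleanly on these data (R-hat < 1.01, no
divergences) in tens of seconds per fit. The interval-coverage study
runs 20 replicates at 130 samples / 20 individuals with truth defined by
a lightly ridge-penalized projection of the generator curves onto the
design (an unpenalized projection can explode on near-collinear bases,
defining unrecoverable "truths"), and uses deliberately diffuse
coefficient priors — with a fixed, non-prior-drawn truth, interval
coverage is a clean check of likelihood and sampler only when the
likelihood dominates the prior. Degenerate inputs fail loudly:
constant predictors, duplicate measurement dates, SG at or below 1.000,
single-chain R-hat requests, constant vectors in correlations.

## Known limitations

* The additive male interval bounds are reproduced verbatim for
  replication but are not valid intervals; use the posterior-sum rows.
* At nine age windows, a Spearman correlation has a sampling SD of
  roughly 0.35 under independence, so the male (decoupled) correlation
  fluctuates considerably across seeds even when truly zero.
* `alpha` has a flat score at 0 in the mean parametrization, so its
  posterior mixes more slowly than other parameters near symmetry.
* The NUTS implementation is single-threaded; full-scale settings
  (5 × 10,000) take tens of minutes per model on one CPU.
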