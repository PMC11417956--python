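# ctxgrowth

Validation pipeline for **urinary CTX-I as a non-invasive bone-growth
marker**, built around the zoo-bonobo study design: longitudinal urine
sampling with specific-gravity (SG) correction, forearm growth-velocity
derivation from repeated length measurements, and hierarchical Bayesian
skew-normal spline regression of both outcomes across age and sex.

CTX-I (C-telopeptide of type I collagen) is released during osteoclastic
bone resorption and can be measured in urine, making it a candidate
non-invasive index of skeletal growth for species where repeated capture
is impossible. Whether it *is* a meaningful growth marker is an empirical
question, answered here in three steps:

1. **Biological variability** — within-individual day-to-day coefficient
   of variation (CV = 100·SD/mean) of repeated same-time samples, and the
   diurnal decline of CTX-I over the 07:00–18:00 collection window.
2. **Age/sex structure** — each outcome `y` (log SG-corrected CTX-I, or
   log forearm growth velocity, FGV) is modeled as

   ```
   y_i ~ SkewNormal(mu_i, sigma, alpha)
   mu_i = beta0 + f(age_i) + male_i · g(age_i) + beta_sex·sex_i
          [+ beta_t·time_i]                       (CTX model only)
          + u[ind_i] + s[ind_i]·age_i + z[site_i]
   ```

   where `f` and `g` are 9-coefficient cubic B-spline smooths (10-knot
   basis, sum-to-zero constrained; female is the reference sex and `g` is
   the male deviation), `u`/`s`/`z` are individual intercepts, individual
   age slopes, and housing-site intercepts, and the skew-normal uses the
   mean parametrization (`mu` = mean, `sigma` = SD, `alpha` = shape).
   Age, sex, and time of day are centered and scaled to two standard
   deviations; age is standardized on the gradient pooled across both
   datasets so the two models share one age scale.
3. **Cross-model correspondence** — the headline check: Spearman rank
   correlation, per sex, between the nine velocity spline estimates and
   the nine CTX spline estimates. A biomarker that tracks bone growth
   produces a strong positive correlation where the coupling exists.

Sampling uses an in-package No-U-Turn Sampler (NUTS) with analytic
gradients, dual-averaging step-size adaptation, and a diagonal mass
matrix, with split-chain Gelman–Rubin (R-hat) and effective-sample-size
diagnostics and posterior predictive checks. A synthetic cohort
generator with known ground truth (sex-specific velocity and CTX age
curves, 25% day-to-day CV, a 0.55 evening/morning concentration ratio,
skew-normal residuals, SG values occasionally below the 1.003 QC
threshold) makes the whole pipeline testable without any external data.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_preprocess.py
python analysis/03_descriptives.py
python analysis/04_fit_models.py          # reduced sampler; --full for 5x10,000
python analysis/05_compare_estimates.py
```

prints (seed 0, reduced 2-chain sampler):

```
cohort written to results/cohort: 81 individuals, 364 forearm measurements, 187 urine samples
retained 182/187 urine samples (5 below SG 1.003; reference SG 1.0141)
derived 283 velocity records; clamped 5 non-positive velocities to 1.94e-05 cm/day
printed-table reproduction: per-female CVs [29.1, 17.1, 31.8, 21.1] -> mean 24.8 %
log_fgv: n=283, 0 divergences, max R-hat 1.007, 36s
log_ctx: n=182, 0 divergences, max R-hat 1.006, 20s
  time-of-day effect: -0.36 (SE = 0.08, lCI = -0.52, uCI = -0.20)
printed table, sex F: r(7) = 0.83, p = 0.008
synthetic cohort, sex F: r(7) = 0.88, p = 0.003
synthetic cohort, sex M: r(7) = -0.27, p = 0.493
```

Reading the output: four SG-corrected samples per female reproduce the
published per-female CVs and their 24.7–24.8% mean; the negative
time-of-day coefficient is the diurnal CTX-I decline; and the female —
but not male — rank correlation between velocity and CTX-I spline
estimates is the validation result: in the generator, female CTX-I is
coupled to growth velocity and male CTX-I is not, and the pipeline
recovers exactly that contrast.

The same stages are available as a CLI (`ctxgrowth simulate | preprocess |
descriptives | fit | report | compare | compare-tables`); `ctxgrowth
report --fast` runs everything end to end into one output directory.

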