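# Methods

## The reactivity model

The package treats resilience as an outcome: the ability to keep
mental-health problems low *given* stressor exposure. Exposure E is a
checklist sum (40 items, 0–5 burden severities), problems P a GHQ-12
total. The population assumption is a linear exposure–symptom relation

```
P_it = b0 + b1 E_it + d0_i + d1_i E_it + SR*_it
```

with participant-level random deviations (d0, d1) from the normative
line and SR\*, the structured reactivity deviation, collecting everything
the analyses are about: stable between-person contributions of
resilience factors, weekly within-person fluctuations, a diagnosis
shift, and week-level noise. The observed SR score is the residual of P
on the *estimated* line; estimating the line by the fixed effects of a
random-intercept/random-slope mixed model (repeated data) or OLS (one
row per person) makes SR a relative, sample-normed quantity. Adding a
quadratic exposure term is checked (partial F cross-sectionally, ML
likelihood-ratio χ²₁ longitudinally) but the model is linear by default.

GHQ-12 is scored 0-1-2-3 (range 0–36): Likert scoring is the common
choice for severity sums and maximizes variance; the alternative binary
scoring would only rescale the outcome, and all reported coefficients
are standardized anyway. Scale scores tolerate up to 20% missing items
(implicit mean imputation from the respondent's own answers); below that
the score is missing and rows are dropped listwise per model.

## Analysis conventions

- **Standardization.** Every reported coefficient is fully standardized.
  For mixed models, the outcome and the raw time-varying predictor are
  z-scored on the analysis rows *before* the within/between
  decomposition, so the person-mean and demeaned parts share one scale.
- **Within/between decomposition.** Person means are taken over all
  retained follow-up weeks (the "average weekly mode"); demeaned values
  are deviations from that mean. The decomposition is exact by
  construction.
- **Random structure and inference.** Weekly models use a participant
  random intercept plus a random slope on the demeaned predictor with
  free correlation; on non-convergence the structure is simplified
  stepwise (drop the correlation, drop the slope, finally OLS), each
  step logged. Fixed-effect p-values use the Wald z approximation —
  identical across ecosystems and adequate at 200 participants;
  degrees-of-freedom corrections would change nothing at this scale.
  REML is used for reporting, ML for likelihood-ratio comparisons.
- **Lag definition.** Lags are in assessment index, not calendar days;
  the 5–9-day spacing filter has already enforced near-weekly gaps.
  Lagged pairs are formed only from consecutive retained weeks, and the
  "previous sampling time point" of the spacing rule is read as the
  previous *retained* assessment.
- **Autoregressive follow-up.** A significant lagged effect is re-tested
  with the outcome's raw week-t value as an additional fixed effect. The
  week-t control deliberately enters *uncentered*: its person mean would
  average over future outcome weeks and act as a collider (verified in
  simulation, where the centered control produced large spurious
  effects).
- **Mediation.** Baron–Kenny paths (a from `m ~ x`, b and c′ from
  `y ~ x + m`, c from `y ~ x`, all with the same covariates); the
  indirect effect is a·b with a distribution-of-the-product interval
  computed by seeded Monte Carlo (default 10⁶ draws, quantile
  interpolation) rather than the classical tables — numerically
  convergent to the same distribution and reproducible everywhere.
  Significance is decided by the CI excluding zero; all paths are still
  reported. The weekly (1-1-1) variant uses fixed slopes and random
  intercepts for both paths; random-slope covariance refinements are out
  of scope. Mediation models use the same screened covariate set in all
  three regressions.
- **Covariate screen.** Age, gender and survey language are always
  included; further candidates pass a univariate likelihood-ratio test
  at p < .2 (OLS cross-sectionally; ML random-intercept mixed model on
  weekly SR longitudinally). Under the null this retains ~20% of noise
  candidates by construction — the screen is deliberately liberal.
- **Outlier gate.** Squared Mahalanobis distances from the sample mean
  and covariance of (E, P); exclusion above the χ²₂ 0.999 quantile
  (13.8155). Pooled participant-weeks enter the gate for the
  longitudinal line (per-week covariances would be noisier and the gate
  targets the pooled distribution the line is fitted on). Excluded rows
  get no SR score unless explicitly requested.
- **Group contrast.** The diagnosed-vs-not SR contrast uses Student's
  pooled-variance t with df = n₁+n₂−2 (the convention matching
  reported df of that analysis style), computable from raw data or from
  group summaries alone.

## The synthetic cohort

The generator emulates the data structure of a weekly stress survey:

- **Exposure.** Items occur with per-person probability p + qᵢ
  (default p = .35, between-person SD .08), severities uniform on 1–5;
  E's mean, between- and within-person variances follow in closed form.
  Defaults give E ≈ 42 ± 14, a realistic checklist regime.
- **Symptoms.** Default line P = 8 + 0.12·E with random-intercept SD 2,
  random-slope SD 0.015 and residual SD 3 puts P at ≈ 13 ± 5 on the
  0–36 scale. Integer GHQ items are emitted by quantizing P (a
  continuous-response switch exists for algebraic checks: recovery and
  coverage studies use it to keep closed-form truths exact; the
  quantized path is exercised by the fixed-point and pipeline tests).
- **Resilience factors.** Nine factors; each is `mean + uᵢ + w_it` with
  AR(1) weekly dynamics (lag-1 correlation 0.3 by default — the minimal
  stationary process with tunable persistence; the data motivating the
  design imply stability but no particular process). Variance ratios
  put implied intraclass correlations at 0.64–0.85. Baseline "styles"
  are the person component plus optional measurement noise, so
  prospective style effects exist by construction. Effects on SR are
  parameterized in symptom units per SD of the relevant latent
  component, at three levels: between, contemporaneous within, lagged
  within.
- **Mediation chain.** Between- and within-person latents of the
  support and appraisal factors share correlation a (default .35); the
  appraisal and support SR effects then are the true b and c′ paths.
- **Calibration.** `implied_standardized_effect` computes, in closed
  form, the standardized estimand each analysis targets (including the
  AR cross-terms and the finite-T person-mean variance), and
  `calibrate_effect` inverts it so simulation studies can inject exact
  standardized effects (−0.25 between, −0.3 within, …). The formulas
  are probability limits that are exact in the single-effect designs the
  recovery suites use; they were additionally verified against
  mega-sample (n = 20 000–40 000) estimates.
- **Logistics.** Monotone dropout (default 7%/week), visit dates at
  7-day intervals with uniform integer jitter (default ±1 day; ±2
  exercises the spacing filter), diagnosis prevalence .33 with an
  additive SR shift (default 1.7 symptom units ≈ 0.4 SD, mirroring the
  diagnosed-vs-not contrast magnitude typical for such cohorts).

What the generator does *not* emulate: nonstationary pandemic phases,
country or language effects on the outcome, non-random dropout, floor
and ceiling effects beyond mild quantization clipping, and item-level
factor structure of the questionnaires (modes are emitted as scale
scores). Passing recovery tests therefore show estimator correctness
under the stated model, not robustness to those real-data features.

## Mixed-model estimation

All mixed models in the pipeline share one family: a single grouping
factor (participant), a random intercept and at most one random slope.
`srres.lmm` implements profiled ML/REML for exactly this family —
fixed effects and the residual variance are profiled out, the optimizer
searches only the ≤3 entries of the relative Cholesky factor, and
per-group sufficient statistics with the Woodbury identity make each
evaluation O(groups). A fit takes ~20–30 ms, which is what makes the
replicate-heavy validation suites (thousands of mixed fits) practical.
The solver is validated against `statsmodels.MixedLM` (fixed effects,
standard errors, variance components, ML log-likelihood and LR
statistics agree to numerical tolerance); standard errors are
conditional on the estimated covariance parameters, the same convention
as lme4 and statsmodels. Random-effect variances may sit exactly on the
zero boundary (L-BFGS-B with nonnegativity bounds; a Nelder–Mead retry
guards rough profiles).

## Validation study design

The simulation suites run at reduced scale (n = 200 participants, T = 5
follow-up weeks, 200–500 replicates per scenario; ICC recovery at
n = 500) — large enough for binomial error on a coverage proportion of
~1%, small enough to keep the full suite within minutes. Null scenarios
check the 5% type-I rate; coverage bands of 92–98% acknowledge the Wald
approximation and the line-estimation step inside the SR outcome.

Two designed deviations deserve note:

- **ICC recovery** uses serially uncorrelated weekly noise, because the
  variance-components ICC target b²/(b²+w²) is the estimand only
  without within-person autocorrelation; with AR(1) noise at T = 5 part
  of the serial correlation is attributed to the person level (an
  upward shift of ~0.05 at ρ = 0.3 — a property of the estimand, not an
  estimator bug).
- **The persistence-only discriminant experiment** (exposure feeds a
  coping factor contemporaneously; the factor persists; the raw lagged
  exposure effect should vanish once the factor's week-t value is
  controlled) runs on a longer panel (T = 15, persistence 0.85,
  exposure feed 0.06 SD). The reason is a genuine estimator artifact:
  the demeaning window of the within estimator contains week t+1, so
  contemporaneous feedback couples the demeaned exposure at t to the
  outcome — a first-order negative bias of order ee/(T−1) in the
  adjusted model. At T = 5 this artifact rivals the raw signal and no
  effect size produces the clean pattern; at T = 15 it is ~0.4 SE at
  the designed effect size and the pattern holds in ~95% of replicates.
  The configuration was fixed by this a-priori power analysis. The
  practical lesson carries over to real analyses: near-significant
  negative coefficients in autoregressive follow-ups of short panels
  can be demeaning artifacts rather than substantive effects.

## Degenerate inputs and numerical choices

Zero exposure variance, singular (E, P) covariance (with a hint to
jitter), constant candidate covariates, within-person-constant
predictors, all-singleton grouping (falls back to OLS, where mixed and
OLS lines coincide for any feasible weighting), zero pooled variance in
the group contrast, and sub-3-observation samples all raise or flag
explicitly rather than returning garbage. Quantile interpolation in the
Monte Carlo interval is linear; z-scoring uses the n−1 sample SD;
tertile boundaries are inclusive with ties kept, so the exposure
subsample is never smaller than two thirds.
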