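# Methods

## The problem

A published absolute-risk equation (a Framingham-style or China-PAR-style
stroke score) is a sex-specific Cox proportional-hazards model summarised by
three ingredients: log hazard ratios `beta_j` for (possibly transformed)
covariates, the derivation cohort's covariate means `xbar_j`, and the baseline
survival `S0(t)` at the prediction horizon for a subject at those means. The
predicted probability of an event by the horizon is

    risk = 1 - S0(t) ^ exp(LP - LPbar),   LP = sum_j beta_j x_j,  LPbar = sum_j beta_j xbar_j.

Applied to a new population, such a score can fail in three distinct ways —
wrong baseline risk level, wrong covariate means, wrong covariate weights —
and the package implements the corresponding three-tier updating procedure
plus the full validation battery used to diagnose each failure.

## Model tiers

* **original** — the score exactly as published.
* **adjusted** — `xbar_j` and `S0(t)` replaced by cohort values; coefficients
  kept bitwise unchanged. The cohort baseline survival is estimated by the
  Breslow estimator with the published linear predictor held fixed (entered
  as an offset), evaluated at the cohort covariate means. This keeps
  "coefficients unchanged" literally true while re-estimating only the level.
* **recalibrated** — coefficients refit on the cohort by Cox partial
  likelihood with the identical term structure (transforms, conditions and
  assume-zero flags preserved); means and baseline survival cohort-derived as
  in the adjusted tier. A term whose covariate the cohort never measured
  (assume-zero, hence an all-zero column) is inert for scoring; it keeps its
  published coefficient and is excluded from the refit design.

## Survival primitives

Kaplan–Meier estimation delegates to lifelines. The Cox fitter is a Newton
iteration on the partial likelihood with Breslow tie handling by default
(Efron optional), step-halving on overshoot, convergence when the relative
change in log partial likelihood falls below 1e-9 (max 100 iterations), and
standard errors from the observed information. Columns are centred internally
for numerical stability; estimates are equivariant to covariate rescaling and
invariant to time rescaling. lifelines' `CoxPHFitter` is used in the test
suite as an independent cross-check of coefficients and standard errors, never
as the implementation. Follow-up time is in years throughout; "event by the
horizon" means `time <= horizon`.

## Validation battery

* **Calibration.** Subjects are split into deciles of predicted risk
  (quantile split; indistinguishable risks merge groups with a warning). Per
  group, the Kaplan–Meier observed risk `k_g = 1 - S_g(horizon)` is compared
  with the mean predicted risk `pbar_g`:

      chi2 = sum_g n_g (k_g - pbar_g)^2 / (pbar_g (1 - pbar_g)),  df = G - 2.

  With G = 10 the 1% critical value is 20.09, i.e. chi-square above ~20 flags
  significant lack of calibration. A group with degenerate `pbar_g` has its
  variance floored at `1/(4 n_g)` and is flagged rather than dropped.

  *Null distribution.* The `G - 2` reference describes a model **fit on the
  same data** (the classic Hosmer–Lemeshow setting; here the recalibrated
  tier): simulated at n = 2000 the refit-per-replicate statistic has mean
  ~9.0 and exceeds 20.09 in ~1% of replicates. When the evaluated score is an
  *external* fixed model that happens to be exactly true, each decile term is
  a full chi-square(1) and the statistic's mean is close to G (~10.4 measured,
  slightly above 10 because the binomial variance understates Kaplan–Meier
  variance under censoring), with ~4–5% of replicates beyond 20.09. Users
  comparing an untouched external score against the chi-square(G-2) scale
  should expect this mild conservatism in reverse.

* **Discrimination.** C statistic = probability that a random event subject
  outranks a random non-event subject, ties half-weighted; computed via
  midranks, variance by the DeLong structural components. Differences between
  paired scores use the DeLong covariance of those components. The test suite
  verifies exact numeric agreement with R's pROC on a fixed instance and
  coverage of the true difference in simulation.

* **Reclassification.** Category-less NRI: "up" means the new risk is
  strictly greater; ties move neither way but remain in denominators. Event
  NRI = (up_e - down_e)/n_e; non-event NRI = (down_ne - up_ne)/n_ne; total is
  their sum (range -2..2). CIs are asymptotic normal by default (multinomial
  variance of the net proportions); a seeded bootstrap (2000 resamples) is
  optional. IDI is the change in discrimination slope with the SE from paired
  per-subject differences.

* **Binary status at the horizon.** C/NRI/IDI need a binary outcome: event
  subjects had the event by the horizon, non-event subjects were followed at
  least to the horizon. Subjects censored earlier without an event carry no
  binary outcome; they are excluded from these statistics and their count is
  reported on every result. Kaplan–Meier handles censoring on the calibration
  side. IPCW-weighted variants are out of scope.

## Synthetic cohorts

The generator emulates a community cohort of older adults used for external
validation of stroke scores. Defaults (chosen once, from the emulated study's
reported structure):

* n = 2,468 pre-exclusion subjects, 44.6% men; per-sex truncated-normal
  continuous covariates (age, SBP, total cholesterol, HDL-C, waist) and
  Bernoulli flags (urban, antihypertensive treatment, diabetes, smoking,
  CVD history) at the reported analysis-set moments. Age is drawn on
  [55, 95] with the underlying location back-solved so that the *post-
  exclusion* (55–84) mean matches the reported value.
* covariates are drawn independently — only marginals are reported for the
  emulated study, so independence is the honest default (no correlation
  structure is claimed or tested).
* events: time-to-stroke from a proportional-hazards model, cumulative hazard
  `(lambda t)^shape * exp(LP - LPbar)` with shape 1 (exponential) by default;
  baseline hazards 0.0172/yr (men) and 0.0155/yr (women), set so the analysis
  cohort accrues roughly 105–110 strokes among ~1,200–1,250 subjects — the
  reported scale of ~106 strokes in 1,203. Per-sex rates mirror the reported
  higher incidence in men.
* censoring: administrative at 5.1 years plus 12.5% uniform early dropout
  (the reported loss to follow-up).
* exclusion cascade in fixed order — prior stroke, age outside 55–84,
  missing laboratory data — with flag rates from the reported counts
  (297/2468 and 815/2018). The analysis n lands near 1,240 rather than
  exactly 1,203 because the over-84 fraction implied by the age marginal
  (~2%) is smaller than the reported over-84 count; the cascade arithmetic
  itself is verified exactly on a cohort constructed with the reported
  counts.

What passing tests on these cohorts do **not** show about real data:
correlated risk factors, non-proportional hazards, informative censoring,
measurement error, and secular trends are all absent by construction.

`miscalibration_scenarios` perturbs the generating truth in exactly one
component — shifted means, doubled baseline hazard, or re-weighted
coefficients — so tests can verify that the adjusted tier repairs level
miscalibration and only the recalibrated tier restores discrimination (the
re-weighted scenario moves the evaluated score's C about 0.05–0.08 below the
oracle's; refitting recovers it to within 0.02).

## Numerical and design choices

* Breslow ties by default (classical risk-equation convention); Efron
  available.
* Horizon conversion uses the constant-hazard power rule
  `S0(t') = S0(t)^(t'/t)` unless a cohort-derived baseline curve is supplied;
  extrapolation beyond a curve's support requires an explicit flag.
* Missing predictors are handled per term and opt-in
  (`assume_zero_if_missing`), never globally, so silent imputation is
  impossible for ordinarily measured covariates.
* Fewer than 10 events per refit term warns rather than errors — validation
  cohorts are often small and the user should decide.
* Everything is sex-specific end to end; the pipeline scores and validates
  men and women separately.
* Problem sizes in the acceptance computations (n = 2000 cohorts, 100–500
  replicates, n = 4000 for the discrimination scenario) were chosen as the
  smallest sizes at which the Monte-Carlo noise is well inside the stated
  tolerances.

## Known limitations

* No competing risks (death before stroke is treated as censoring).
* No IPCW versions of C/NRI/IDI; the censored-before-horizon exclusion count
  makes the complete-case choice auditable.
* The analytic NRI variance ignores the (small) covariance induced by
  scoring both models on the same subjects beyond the movement categories;
  the bootstrap option sidesteps this.
* Published reclassification tables occasionally print NRI values that are
  inconsistent with their own movement counts (rounding in the source); this
  package always reports the count-implied formula values.
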