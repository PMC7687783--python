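# Methods

## The model being validated

The package encodes a published prognostic model for survival of people
living with HIV/AIDS after starting combination antiretroviral therapy
(ART).  It is a Cox-type score over three baseline predictors:

```
PI = −0.005580907·CD4 (cells/µL) − 0.005368102·Hb (g/L)
     + 1.019669556·[viral load 200–<1000 copies/mL]
     + 2.608969326·[viral load ≥1000 copies/mL]
```

with survival predictions `S(t) = S0(t)^exp(PI)` anchored at
`S0(1) = 0.980222074`, `S0(2) = 0.972736744`, `S0(3) = 0.964896148`, and a
nomogram points scale `score = 108.3333333 + 19.90914787·PI`.  An extended
variant adds literature-derived age-band and gender terms
(`+0.2382292` for age 40–<60, `+0.5866749` for age ≥60, `−0.3566749` for
female).  All constants are stored at full precision and never re-fitted;
the coefficients come from a nomogram digitization, which is why the score
mapping and baseline survivals look like arbitrary decimals.

Conventions where the source is ambiguous: viral-load bands and age bands
are half-open (`[200, 1000)`, `[40, 60)`), so exactly 1000 copies/mL is the
high category and exactly 40/60 years moves a patient up a band.  The
risk-group cutoffs on the points scale were never published; they are
configuration with no default, and any operation needing groups fails fast
when they are unset.  Absolute predictions are limited to horizons 1/2/3
years (the published baseline survivals); rank-based discrimination uses
the PI alone and works at any horizon.

## Validation statistics

All estimators are implemented directly on numpy arrays; lifelines and
scikit-survival serve only as independent cross-checks in the test suite.

* **Kaplan–Meier / Nelson–Aalen** — standard product-limit and cumulative-
  hazard estimators; step functions are right-continuous and evaluated by
  index lookup.  Median follow-up uses the reverse Kaplan–Meier method
  (censoring as the event); when the reverse curve never reaches a
  quantile (e.g. everyone died) the summary is flagged undefined rather
  than extrapolated.
* **Harrell's C** — usable pairs are those where the shorter time is an
  event, or times are tied with exactly one event; tied event times are
  unusable and tied scores count ½.  The default standard error is an
  exact delete-one jackknife: each subject's contribution to the
  numerator and denominator is accumulated during the O(n²) pair pass, so
  every leave-one-out estimate is exact, not approximated.  A
  nonparametric bootstrap (200 resamples) is available as an option; the
  two agree well in tests.  The jackknife was chosen as default because it
  is deterministic and costs one pass, where bootstrapping an O(n²)
  statistic inside a 50-imputation pipeline is prohibitive.
* **Time-dependent C at horizon t** — cases are subjects with an observed
  event by t, comparators those still under observation beyond t; each
  pair is weighted by the inverse probability of remaining uncensored,
  `1/(G(T_case−)·G(t))`, with `G` the Kaplan–Meier estimate of the
  censoring distribution.  With no censoring before t all weights are 1
  and the estimator provably equals the plain truncated concordance — that
  equivalence, not a package default, pins the definition, and it is
  asserted against an exhaustive pair-enumeration oracle.
* **Calibration** — subjects are binned by quantiles of predicted survival
  (default 10 bins); each bin's observed survival is its own Kaplan–Meier
  estimate at the horizon.  The sign convention is observed − predicted:
  positive means the model underestimates survival (overestimates risk).
  Both the bin-average and the patient-weighted average are reported; the
  bin average is the default summary.  Bins with nobody under observation
  at the horizon are flagged rather than silently dropped.
* **Mortality rate** — events per 1000 person-years with an exact Poisson
  interval from chi-square quantiles (`χ²(α/2, 2k)/2` to
  `χ²(1−α/2, 2k+2)/2`).
* **Rubin's rules** — pooled estimate is the mean over imputations; total
  variance within + (1+1/m)·between; intervals use Barnard–Rubin
  large-sample degrees of freedom, collapsing to normal when the
  between-imputation variance is zero.  C-statistics are pooled on the
  logit scale (they live in [0,1]) with delta-method variances, then
  back-transformed.

## Multiple imputation

Chained equations, fully seeded.  The imputation model contains all
predictors and auxiliary covariates plus the outcome, represented — as is
standard for survival outcomes — by the Nelson–Aalen cumulative hazard at
each subject's observed time together with the event indicator.
Laboratory values are log-transformed first (positive, right-skewed).
Continuous variables are completed by predictive-mean matching against a
Bayesian linear-regression draw with a donor pool of 5; the categorical
viral load by a draw from multinomial-logistic predicted probabilities.
Defaults: m = 50 completed datasets, 10 chained passes.  The iteration
count, donor-pool size and per-variable methods are conventional choices
(the protocol being reproduced states only m); they are deliberate
defaults, not tuned values.  Observed cells are never altered, and this is
asserted cell-wise in tests.

Two deterministic viral-load scenarios bracket the imputation assumptions:
set every missing value to <200 copies/mL, or draw missing categories from
the derivation cohort's distribution (78.7/3.0/18.3%).

## The synthetic cohort generator

The registry behind the original validation is not public, so experiments
run on synthetic cohorts with known truth.  The generator emulates the
published cohort description:

* CD4, hemoglobin, age and four auxiliary labs are log-normal,
  moment-matched to the printed medians and IQRs (CD4 209 [72–319],
  Hb 137 [116–150], age 34.3 [27.2–44.0]); a Gaussian copula gives the
  labs mild positive correlation (CD4–CD8 0.4, CD4–WBC 0.3, Hb–WBC 0.25)
  so auxiliaries genuinely inform the imputation model.  A log-normal
  cannot match an asymmetric IQR exactly; the median and the IQR ratio are
  matched.
* Viral-load categories use the proportions observed among non-missing
  registry values (1.6/2.4/96.0%); gender is 81.5% male.  Ages ≤15 are
  resampled (the cohort is adult by inclusion).
* Event times follow the proportional-hazards model
  `S(t|x) = exp(−λ·t^k·e^PI)` with the published coefficients as the
  default truth and a Weibull baseline with shape k = 0.7 (declining
  hazard after ART start).  The scale λ = 0.008179574 was calibrated once,
  by Monte-Carlo root finding over the covariate distribution, so that
  cumulative 3-year mortality is 3.72%; with the censoring process below
  this lands the realized mortality rate near 10–11 per 1000 person-years
  and 5/10/15-year cumulative mortality near 5.2/8.3/10.7% — close to the
  reported 5.11/8.96/11.35% without being fitted to them.
* Censoring combines era-based administrative follow-up (entry eras
  2004–07/2008–11/2012–15/2016–19 with probabilities
  0.034/0.133/0.347/0.486 and follow-up windows down from ~16 to ~0–4
  years) and exponential dropout at 0.02/year.  The real registry's
  dropout process is unobservable; this rate is a free parameter chosen
  once as plausible loss to follow-up.
* Missingness: viral load is masked missing-at-random with probability
  depending on entry era (earlier era → more missing; logit slope −0.9 per
  era step, intercept solved exactly for the 85.7% overall target).  CD4
  and hemoglobin are masked completely at random at the printed 1.1% and
  1.4%.

What the generator does **not** emulate: competing risks (all deaths are
one endpoint), measurement error and within-patient longitudinal lab
trajectories, informative censoring, calendar-time trends in treatment
efficacy, and the real (unknown) joint distribution of viral load with the
other predictors — the true registry association is unobservable at 86%
missingness.  Passing tests therefore show the estimators and the
methodological arguments are correct under a faithful proportional-hazards
world, not that the synthetic cohort reproduces the registry's exact
numbers.

## Experiments

* **Case–control bias.**  A development cohort is sampled two ways: a 1:4
  matched case–control subsample (all deaths, four controls each matched
  on gender exactly and age within ±5 years — the source study's caliper
  is unknown), and a random subcohort of the same size.  A three-predictor
  Cox model fitted on each (partial likelihood with Breslow ties; Breslow
  baseline at zero covariates) is validated on an independent population
  cohort.  The enriched arm's baseline hazard reflects a 20% event
  fraction, so it overestimates mortality: mean (observed − predicted
  survival) comes out positive; the random arm centres at zero.  Cases
  that cannot be fully matched are dropped and counted, mirroring how
  matched designs shed subjects.
* **Added value of age/gender.**  Cohorts are generated with the published
  extended coefficients as part of the truth; Harrell's C of the
  three-predictor score is compared with the extended score on the same
  cohort.  Matching on age and gender during development discards exactly
  this signal, so the extended model wins whenever the generating effects
  are nonzero, and the difference vanishes when they are zero.

## Numerical and design choices

* Problem sizes: experiments and self-consistency checks use cohorts of
  n = 20 000 with 5 replicate seeds; parameter-recovery fits use fully
  observed cohorts (no censoring, exponential baseline) so every subject
  contributes an event, and assert on the mean of 5 replicate fits — the
  natural design for checking a fitter against known truth.  The MI
  workflow check uses n = 2500 with m = 10.
* Zero-variance design columns carry no partial-likelihood information;
  the Cox wrapper drops them with a warning and reports coefficient 0.
* Quantile bin edges with ties collapse bins rather than erroring.
* Step-function lookups are right-continuous; censoring-distribution
  lookups for IPCW use the left limit `G(t−)` for cases.
* Generated event times are floored at 1e−6 years to keep times strictly
  positive.
* Seeds: every stochastic component takes an explicit seed or generator;
  child seeds are spawned via `SeedSequence` and kept below 2³¹.

## Known limitations

* The IPCW time-dependent concordance assumes censoring independent of the
  score; under strongly covariate-dependent censoring the weights would
  need to condition on covariates.
* Rubin pooling of the time-dependent C grid reports the across-imputation
  mean and range rather than a full logit-scale pooled interval (the
  per-horizon standard errors are not estimated by default).
* The imputation model is a main-effects model; interactions or nonlinear
  relations in the data would make it uncongenial.
* Risk-group summaries depend entirely on user-supplied cutoffs, since the
  published thresholds are not available.
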