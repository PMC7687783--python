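# hivsurv

External validation of a published prognostic model for survival of people
living with HIV/AIDS on antiretroviral therapy (ART), built as a reusable
pipeline plus simulation experiments.

## The problem

A nomogram-based Cox model predicts survival after ART initiation from
three baseline labs — CD4 count, hemoglobin, and categorized HIV viral
load.  It was developed on a 1:4 matched nested case–control sample with
age and gender used for matching.  Validating such a model on an
independent cohort raises exactly the questions this package implements:

* **Discrimination** — Harrell's overall C and an IPCW time-dependent
  (truncated) concordance at fixed horizons.
* **Calibration** — Kaplan–Meier observed vs predicted survival at 1/2/3
  years, in quantile bins, with the convention
  *difference = observed − predicted* (positive ⇒ the model underestimates
  survival, i.e. overestimates mortality).
* **Missing data** — the viral load is missing for most patients in
  registry data; the pipeline runs multiple imputation by chained
  equations (with the Nelson–Aalen cumulative hazard and the event
  indicator in the imputation model), pools with Rubin's rules, and offers
  complete-case and two viral-load scenario analyses as sensitivity runs.
* **Design replay** — synthetic cohorts with known truth demonstrate two
  methodological points: a model developed on an event-enriched matched
  subsample without baseline re-anchoring overestimates mortality, and
  matching on age/gender throws away predictive signal that an extended
  model recovers.

The model itself: `PI = −0.005580907·CD4 − 0.005368102·Hb + 1.019669556·
[VL 200–<1000] + 2.608969326·[VL ≥1000]`, `S(t) = S0(t)^exp(PI)` with
`S0(1/2/3) = 0.980222074 / 0.972736744 / 0.964896148`, and the nomogram
points scale `score = 108.3333333 + 19.90914787·PI`.  See
`docs/methods.md` for the full account.

## Layout

```
src/hivsurv/     model.py       scoring (PI, survival, points, risk groups)
                 metrics.py     KM, Nelson–Aalen, Harrell C, IPCW C,
                                calibration, Poisson CI, Rubin pooling
                 missing.py     chained-equations MI, viral-load scenarios
                 cohort.py      synthetic registry-like cohorts, matched
                                sampling, Cox fitting
                 experiments.py design-replay experiments
                 ingest.py / pipeline.py / cli.py
analysis/        numbered drivers reproducing the full analysis
scripts/         acceptance.py
```

## Worked example

```
$ hivsurv simulate --n 20000 --seed 20200101 --out results/cohort.csv
$ python analysis/02_validate_model.py
ingested 20000/20000 records (0 excluded)
deaths: 942 (4.71%), rate 10.65/1000 PY (95% CI 9.98-11.35)
pooled Harrell C (original): 0.748 (95% CI 0.733-0.763)
pooled Harrell C (extended): 0.741 (95% CI 0.726-0.756)
calibration at 1.0 y: mean(observed - predicted) = +2.45% (worst bin +5.66%)
calibration at 2.0 y: mean(observed - predicted) = +2.98% (worst bin +6.89%)
calibration at 3.0 y: mean(observed - predicted) = +3.54% (worst bin +7.89%)
```

Reading this: the synthetic cohort (20 000 patients, ~86% missing viral
load, multiply imputed with m = 20) yields a pooled concordance of about
0.75 — the published coefficients rank patients well, because the synthetic
truth uses those very coefficients.  The calibration differences are
positive and grow with horizon and with predicted risk: the model's
baseline survival comes from an event-enriched development sample, so it
systematically predicts too much mortality against a population cohort —
the central methodological finding, reproduced with known truth.  The
design-replay drivers make the mechanism explicit:

```
$ python analysis/04_case_control_bias.py
seed 0: case-control +0.0756, random subcohort -0.0010
...
case-control arm positive (survival underestimated) in 5/5 seeds

$ python analysis/05_added_value_age_gender.py
seed 0: C original 0.7450 -> extended 0.7533 (Δ +0.0084)
...
extended model better in 5/5 seeds
```

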