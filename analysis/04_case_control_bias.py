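"""Replay the case–control development flaw on synthetic cohorts.

For each seed: fit a three-predictor survival model on a 1:4 matched
case–control subsample of a development cohort (event fraction forced to
20%) and, as a control arm, on a random subcohort of the same size; then
measure calibration of each fitted model on an independent population
cohort.  A positive mean (observed − predicted survival) means the model
underestimates survival, i.e. overestimates mortality.

Writes results/bias_experiment.csv.
"""

from pathlib import Path

import pandas as pd

from hivsurv.cohort import GeneratorConfig, MatchSpec
from hivsurv.experiments import experiment_case_control_bias

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(5)

rows = []
for seed in SEEDS:
    rep = experiment_case_control_bias(GeneratorConfig(n=20_000), MatchSpec(ratio=4), seed=seed)
    rows.append(
        {
            "seed": seed,
            "cc_mean_difference": rep.mean_difference("case_control"),
            "random_mean_difference": rep.mean_difference("random_subcohort"),
            "cc_event_fraction": rep.arms["case_control"]["event_fraction"],
            "n_cases_matched": rep.match_report["n_cases_matched"],
            "n_cases_dropped": rep.match_report["n_cases_dropped"],
        }
    )
    print(f"seed {seed}: case-control {rows[-1]['cc_mean_difference']:+.4f}, "
          f"random subcohort {rows[-1]['random_mean_difference']:+.4f}")

df = pd.DataFrame(rows)
OUT.mkdir(exist_ok=True)
df.to_csv(OUT / "bias_experiment.csv", index=False)
pos = (df["cc_mean_difference"] > 0).sum()
print(f"\ncase-control arm positive (survival underestimated) in {pos}/{len(df)} seeds; "
      f"random-subcohort arm mean {df['random_mean_difference'].mean():+.4f}")
print(f"wrote {OUT / 'bias_experiment.csv'}")
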