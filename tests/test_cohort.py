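"""Synthetic-cohort generator, missingness mask, matched sampling, Cox fit."""

import numpy as np
import pandas as pd
import pytest

from hivsurv.cohort import (
    GeneratorConfig,
    MatchSpec,
    fit_proportional_hazards,
    generate_cohort,
    impose_missingness,
    nested_case_control_sample,
)
from hivsurv.metrics import SurvivalSample, kaplan_meier
from hivsurv.model import ModelParameters, pi_from_frame


class TestGenerator:
    def test_same_seed_identical(self):
        a = generate_cohort(GeneratorConfig(n=500, seed=8))
        b = generate_cohort(GeneratorConfig(n=500, seed=8))
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_pi_matches_model_scoring(self):
        cohort = generate_cohort(GeneratorConfig(n=2000, seed=3))
        pi = pi_from_frame(cohort.data, cohort.config.params)
        assert np.allclose(pi, cohort.truth["true_pi"], atol=0)

    def test_zero_hazard_means_no_events(self):
        cohort = generate_cohort(GeneratorConfig(n=300, seed=1, baseline_scale=0.0))
        assert cohort.data["event"].sum() == 0

    def test_exponential_null_model_matches_closed_form(self):
        # zero coefficients, exponential hazard λ: KM(t) ≈ exp(−λt)
        lam = 0.25
        params = ModelParameters(coef_cd4=0.0, coef_hb=0.0, coef_vl_mid=1e-12, coef_vl_high=2e-12)
        cfg = GeneratorConfig(
            n=30_000, seed=12, params=params, baseline_family="exponential",
            baseline_scale=lam, administrative=False, dropout_rate=0.1,
        )
        cohort = generate_cohort(cfg)
        km = kaplan_meier(
            SurvivalSample(cohort.data["time"].to_numpy(), cohort.data["event"].to_numpy(bool))
        )
        for t in (1.0, 2.0, 4.0):
            assert km.evaluate(t) == pytest.approx(np.exp(-lam * t), abs=0.01)

    def test_covariates_match_emulation_targets(self):
        data = generate_cohort(GeneratorConfig(n=50_000, seed=4)).data
        assert data["cd4"].median() == pytest.approx(209, rel=0.03)
        assert data["hemoglobin"].median() == pytest.approx(137, rel=0.02)
        assert data["age"].median() == pytest.approx(34.3, rel=0.02)
        assert (data["gender"] == "male").mean() == pytest.approx(0.815, abs=0.01)
        assert (data["age"] > 15).all()

    def test_mortality_rate_near_registry_target(self):
        data = generate_cohort(GeneratorConfig(n=50_000, seed=10)).data
        rate = 1000.0 * data["event"].sum() / data["time"].sum()
        assert rate == pytest.approx(11.4, rel=0.2)  # generator calibration band

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            GeneratorConfig(n=0)
        with pytest.raises(ValueError, match="distribution"):
            GeneratorConfig(vl_probs=(0.5, 0.2, 0.2))


class TestMissingnessMask:
    def test_zero_target_no_masking(self):
        cfg = GeneratorConfig(n=400, seed=2, vl_missing_target=0.0, cd4_missing=0.0, hb_missing=0.0)
        cohort = generate_cohort(cfg)
        masked = impose_missingness(cohort.data, cfg)
        pd.testing.assert_frame_equal(masked, cohort.data)

    def test_realized_fraction_hits_target(self):
        cfg = GeneratorConfig(n=100_000, seed=6, vl_missing_target=0.857)
        cohort = generate_cohort(cfg)
        masked = impose_missingness(cohort.data, cfg)
        assert masked["viral_load_category"].isna().mean() == pytest.approx(0.857, abs=0.01)

    def test_missingness_depends_on_era(self):
        cfg = GeneratorConfig(n=50_000, seed=6, vl_missing_target=0.6)
        masked = impose_missingness(generate_cohort(cfg).data, cfg)
        frac = masked.groupby("era")["viral_load_category"].apply(lambda s: s.isna().mean())
        assert frac["2004-2007"] > frac["2016-2019"]  # MAR on observed era

    def test_never_remasks_missing_cells(self):
        cfg = GeneratorConfig(n=5000, seed=3, vl_missing_target=0.5)
        cohort = generate_cohort(cfg).data
        once = impose_missingness(cohort, cfg, seed=1)
        twice = impose_missingness(once, cfg, seed=2)
        # cells observed after the second pass were observed after the first
        still = twice["viral_load_category"].notna()
        assert once.loc[still, "viral_load_category"].notna().all()

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="vl_missing_target"):
            GeneratorConfig(vl_missing_target=1.4)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n=8000, seed=20)).data


class TestNestedCaseControl:
    def test_event_fraction_one_fifth(self, cohort):
        sub, report = nested_case_control_sample(cohort, MatchSpec(ratio=4), seed=0)
        assert sub["event"].mean() == pytest.approx(0.2)
        assert report["n_controls"] == 4 * report["n_cases_matched"]

    def test_gender_distribution_matches_cases(self, cohort):
        sub, _ = nested_case_control_sample(
            cohort, MatchSpec(ratio=2, variables=("gender",), calipers={}), seed=1
        )
        cases = sub[sub["event"] == 1]
        controls = sub[sub["event"] == 0]
        case_female = (cases["gender"] == "female").mean()
        control_female = (controls["gender"] == "female").mean()
        assert control_female == pytest.approx(case_female, abs=1e-9)

    def test_age_caliper_respected(self, cohort):
        spec = MatchSpec(ratio=1, variables=("age",), calipers={"age": 5.0})
        sub, report = nested_case_control_sample(cohort, spec, seed=2)
        # with 1:1 matching, check every control is within 5y of some case
        cases = sub[sub["event"] == 1]["age"].to_numpy()
        controls = sub[sub["event"] == 0]["age"].to_numpy()
        for a in controls:
            assert np.min(np.abs(cases - a)) <= 5.0

    def test_zero_caliper_on_continuous_drops_all_cases(self, cohort):
        spec = MatchSpec(ratio=4, variables=("age",), calipers={"age": 0.0})
        sub, report = nested_case_control_sample(cohort, spec, seed=3)
        assert report["n_cases_matched"] == 0
        assert len(sub) == 0

    def test_no_cases_rejected(self, cohort):
        alive = cohort[cohort["event"] == 0]
        with pytest.raises(ValueError, match="no cases"):
            nested_case_control_sample(alive, MatchSpec(), seed=0)


class TestProportionalHazardsFit:
    def test_single_binary_covariate_matches_grid_oracle(self):
        # tiny data; oracle = exhaustive Breslow partial-likelihood grid
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"x": x, "time": times, "event": events})

        def neg_log_pl(beta):
            ll = 0.0
            for i in range(len(times)):
                if events[i]:
                    at_risk = times >= times[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
            return -ll

        grid = np.linspace(-3, 3, 60_001)
        beta_star = grid[np.argmin([neg_log_pl(b) for b in grid])]
        fit = fit_proportional_hazards(df, ["x"])
        assert fit.coefficients["x"] == pytest.approx(beta_star, abs=1e-4)

    def test_constant_covariate_reports_zero(self):
        cohort = generate_cohort(GeneratorConfig(n=300, seed=30)).data
        cohort["flat"] = 1.0
        fit = fit_proportional_hazards(cohort, ["cd4", "flat"])
        assert fit.coefficients["flat"] == 0.0

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="no events"):
            fit_proportional_hazards(df, ["x"])

    def test_consistency_error_shrinks_with_n(self):
        # RMSE of the CD4 coefficient over replicate cohorts drops with n
        truth = ModelParameters().coef_cd4
        rmse = []
        for n in (2000, 8000, 32_000):
            sq = []
            for seed in (1, 2, 3):
                cfg = GeneratorConfig(
                    n=n, seed=seed, administrative=False, dropout_rate=0.0,
                    baseline_family="exponential", baseline_scale=0.5,
                )
                data = generate_cohort(cfg).data
                fit = fit_proportional_hazards(
                    data, ["cd4", "hemoglobin", "viral_load_category"]
                )
                sq.append((fit.coefficients["cd4"] - truth) ** 2)
            rmse.append(np.sqrt(np.mean(sq)))
        assert rmse[2] < rmse[0]

    def test_baseline_survival_anchored_at_zero_covariates(self):
        # generated under the published coefficients: fitted S0 at zero
        # covariates must sit near the generating baseline exp(−λ t^k)
        cfg = GeneratorConfig(n=20_000, seed=44)
        data = generate_cohort(cfg).data
        fit = fit_proportional_hazards(data, ["cd4", "hemoglobin", "viral_load_category"])
        for h in (1.0, 2.0, 3.0):
            expected = np.exp(-cfg.baseline_scale * h**cfg.shape)
            assert fit.baseline_survival[h] == pytest.approx(expected, abs=0.01)
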