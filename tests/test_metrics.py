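"""Validation metrics against hand calculations and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivsurv.metrics import (
    SurvivalSample,
    calibration_table,
    harrells_c,
    kaplan_meier,
    nelson_aalen,
    poisson_rate_ci,
    pool_concordance,
    pool_rubin,
    reverse_km_median_followup,
    time_dependent_c,
)

from conftest import harrell_oracle, truncated_concordance_oracle


# ---------------------------------------------------------------------------
# Kaplan–Meier / Nelson–Aalen
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        km = kaplan_meier(SurvivalSample([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.evaluate(10.0) == 1.0

    def test_hand_product_limit(self):
        # times 1 (event), 2 (censored), 3 (event): S(1)=2/3, S(3)=(2/3)*0=0
        km = kaplan_meier(SurvivalSample([1.0, 2.0, 3.0], [1, 0, 1]))
        assert km.evaluate(1.0) == pytest.approx(2 / 3)
        assert km.evaluate(2.5) == pytest.approx(2 / 3)
        assert km.evaluate(3.0) == 0.0

    def test_duplication_invariance(self, mixed_sample):
        km1 = kaplan_meier(mixed_sample)
        doubled = SurvivalSample(
            np.concatenate([mixed_sample.times] * 2),
            np.concatenate([mixed_sample.events] * 2),
        )
        km2 = kaplan_meier(doubled)
        assert np.allclose(km1.values, km2.values)
        assert np.allclose(km1.times, km2.times)

    def test_matches_lifelines(self, mixed_sample):
        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter().fit(mixed_sample.times, mixed_sample.events)
        km = kaplan_meier(mixed_sample)
        for t in (0.5, 1.0, 2.0, 3.5, 5.0, 6.0):
            assert km.evaluate(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier(SurvivalSample([], []))


class TestNelsonAalen:
    def test_no_events_zero_hazard(self):
        na = nelson_aalen(SurvivalSample([1.0, 2.0], [0, 0]))
        assert na.evaluate(5.0) == 0.0

    def test_single_event_among_n(self):
        na = nelson_aalen(SurvivalSample([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 0]))
        assert na.evaluate(2.0) == pytest.approx(1 / 3)

    def test_brute_force_sum(self, mixed_sample):
        na = nelson_aalen(mixed_sample)
        t, e = mixed_sample.times, mixed_sample.events
        for horizon in (1.0, 2.0, 4.0, 6.0):
            expected = sum(
                (e & (t == u)).sum() / (t >= u).sum()
                for u in np.unique(t[e])
                if u <= horizon
            )
            assert na.evaluate(horizon) == pytest.approx(expected)

    def test_km_na_exponential_relation(self):
        # low-hazard large sample: S(t) ≈ exp(−H(t))
        rng = np.random.default_rng(7)
        t = rng.exponential(50.0, 5000)
        c = rng.uniform(0, 10, 5000)
        obs = np.minimum(t, c)
        ev = t <= c
        s = SurvivalSample(obs, ev)
        km, na = kaplan_meier(s), nelson_aalen(s)
        for h in (2.0, 5.0, 8.0):
            assert km.evaluate(h) == pytest.approx(np.exp(-na.evaluate(h)), rel=1e-3)


class TestReverseKM:
    def test_all_censored_at_five(self):
        fu = reverse_km_median_followup(SurvivalSample([5.0] * 4, [0] * 4))
        assert fu.defined and fu.median == 5.0

    def test_all_died_is_undefined(self):
        fu = reverse_km_median_followup(SurvivalSample([1.0, 2.0, 3.0], [1, 1, 1]))
        assert not fu.defined and fu.median is None

    def test_matches_hand_reverse_product_limit(self):
        # censoring times 2,4 among deaths at 1,3: reverse-KM steps at 2 (3 at risk)
        # and 4 (1 at risk): G(2)=2/3, G(4)=0 -> median follow-up 4
        fu = reverse_km_median_followup(SurvivalSample([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0]))
        assert fu.median == 4.0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

class TestHarrellsC:
    def test_perfect_ranking(self):
        s = SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1])
        assert harrells_c(s, n_bootstrap=0).estimate == 1.0

    def test_identical_scores_give_half(self):
        s = SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], [2, 2, 2, 2])
        assert harrells_c(s, n_bootstrap=0).estimate == 0.5

    def test_hand_enumerated_five_sixths(self):
        s = SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 1, 2])
        r = harrells_c(s, n_bootstrap=0)
        assert r.estimate == pytest.approx(5 / 6)
        assert r.n_usable_pairs == 6

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            harrells_c(SurvivalSample([1, 2], [0, 0], [1, 2]), n_bootstrap=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 50)
        times = rng.integers(1, 12, n).astype(float)  # integer times force ties
        events = rng.uniform(size=n) < 0.6
        scores = rng.integers(0, 6, n).astype(float)  # tied scores too
        num, den = harrell_oracle(times, events, scores)
        if den == 0:
            return
        r = harrells_c(SurvivalSample(times, events, scores), n_bootstrap=0)
        assert r.estimate == pytest.approx(num / den, abs=1e-12)
        assert r.n_usable_pairs == den

    def test_bootstrap_ci_brackets_estimate(self, mixed_sample):
        r = harrells_c(mixed_sample, se_method="bootstrap", n_bootstrap=100, seed=0)
        assert r.standard_error > 0
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_jackknife_se_agrees_with_bootstrap(self):
        rng = np.random.default_rng(8)
        n = 400
        times = rng.exponential(2.0, n)
        cens = rng.uniform(0, 6, n)
        obs = np.minimum(times, cens)
        events = times <= cens
        scores = -times + rng.normal(0, 1.5, n)
        s = SurvivalSample(obs, events, scores)
        jk = harrells_c(s, se_method="jackknife")
        bs = harrells_c(s, se_method="bootstrap", n_bootstrap=300, seed=2)
        assert jk.estimate == bs.estimate
        assert jk.standard_error == pytest.approx(bs.standard_error, rel=0.25)
        assert jk.ci_low <= jk.estimate <= jk.ci_high

    def test_matches_sksurv(self, mixed_sample):
        from sksurv.metrics import concordance_index_censored

        expected = concordance_index_censored(
            mixed_sample.events, mixed_sample.times, mixed_sample.scores
        )[0]
        r = harrells_c(mixed_sample, n_bootstrap=0)
        assert r.estimate == pytest.approx(expected, abs=1e-12)


class TestTimeDependentC:
    def test_equals_truncated_oracle_without_censoring(self):
        rng = np.random.default_rng(3)
        n = 200
        times = rng.exponential(2.0, n)
        scores = rng.normal(size=n)
        events = np.ones(n, dtype=bool)
        s = SurvivalSample(times, events, scores)
        for h in (0.5, 1.0, 2.0):
            expected = truncated_concordance_oracle(times, events, scores, h)
            assert time_dependent_c(s, h).estimate == pytest.approx(expected, abs=1e-12)

    def test_perfect_separation_is_one(self):
        times = np.array([0.5, 0.8, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0, 0], dtype=bool)
        scores = np.array([10.0, 9.0, 1.0, 2.0, 0.5])
        assert time_dependent_c(SurvivalSample(times, events, scores), 1.0).estimate == 1.0

    def test_no_cases_by_horizon_rejected(self):
        s = SurvivalSample([2.0, 3.0, 4.0], [1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="no events"):
            time_dependent_c(s, 1.0)

    def test_effect_size_drives_estimate_toward_half(self):
        from hivsurv.cohort import GeneratorConfig, generate_cohort
        from hivsurv.model import ModelParameters, pi_from_frame

        ests = []
        for scale in (1.0, 0.3, 0.0):
            p = ModelParameters()
            params = ModelParameters(
                coef_cd4=p.coef_cd4 * scale,
                coef_hb=p.coef_hb * scale,
                coef_vl_mid=p.coef_vl_mid * scale,
                coef_vl_high=p.coef_vl_high * scale,
            )
            cfg = GeneratorConfig(n=6000, seed=17, params=params)
            c = generate_cohort(cfg)
            pi = pi_from_frame(c.data, p)  # score with the full-strength model
            s = SurvivalSample(c.data["time"].to_numpy(), c.data["event"].to_numpy(bool), pi)
            ests.append(time_dependent_c(s, 3.0).estimate)
        assert ests[0] > ests[1] > ests[2]
        assert ests[2] == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def _sample(self, n=4000, seed=5):
        rng = np.random.default_rng(seed)
        surv = rng.uniform(0.55, 0.98, n)  # per-subject true survival at t=1
        died = rng.uniform(size=n) > surv
        times = np.where(died, rng.uniform(0.01, 1.0, n), rng.uniform(1.001, 5.0, n))
        return SurvivalSample(times, died | (times <= 1.0)), surv

    def test_true_predictions_center_at_zero(self):
        sample, surv = self._sample()
        tab = calibration_table(surv, sample, 1.0, n_bins=10)
        assert abs(tab.mean_difference) < 0.02  # Monte-Carlo error only

    def test_downshifted_predictions_show_positive_difference(self):
        sample, surv = self._sample()
        delta = 0.05
        base = calibration_table(surv, sample, 1.0, n_bins=10)
        shifted = calibration_table(surv - delta, sample, 1.0, n_bins=10)
        # same subjects fall in the same quantile bins, so the effect is exact
        assert shifted.mean_difference == pytest.approx(base.mean_difference + delta, abs=1e-9)

    def test_bin_counts_sum_to_n(self, mixed_sample):
        pred = np.linspace(0.2, 0.9, len(mixed_sample))
        tab = calibration_table(pred, mixed_sample, 2.0, n_bins=3)
        assert tab.table["n"].sum() == len(mixed_sample)

    def test_sign_convention_observed_minus_predicted(self):
        # nobody dies; predictions of 0.8 must give difference exactly +0.2
        s = SurvivalSample(np.full(50, 2.0), np.zeros(50, dtype=bool))
        tab = calibration_table(np.full(50, 0.8), s, 1.0, n_bins=2)
        assert tab.mean_difference == pytest.approx(0.2)

    def test_empty_at_risk_bin_flagged(self):
        # the low-prediction bin's subjects are all gone before the horizon
        times = np.array([0.2, 0.3, 0.4, 5.0, 6.0, 7.0])
        events = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        pred = np.array([0.1, 0.12, 0.15, 0.9, 0.92, 0.95])
        tab = calibration_table(pred, SurvivalSample(times, events), 1.0, n_bins=2)
        assert tab.flagged_bins == [0]


# ---------------------------------------------------------------------------
# rates and pooling
# ---------------------------------------------------------------------------

class TestPoissonRate:
    def test_zero_events(self):
        r = poisson_rate_ci(0, 100.0)
        assert r.rate == 0.0 and r.ci_low == 0.0 and r.ci_high > 0

    def test_printed_registry_rate(self):
        r = poisson_rate_ci(743, 65037.0)
        assert r.rate == pytest.approx(11.42, abs=0.005)
        assert r.ci_low == pytest.approx(10.62, abs=0.005)
        assert r.ci_high == pytest.approx(12.28, abs=0.005)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError, match="exposure"):
            poisson_rate_ci(5, 0.0)


class TestRubin:
    def test_identical_estimates(self):
        p = pool_rubin([0.7, 0.7, 0.7], [0.01, 0.01, 0.01])
        assert p.estimate == pytest.approx(0.7, abs=1e-12)
        assert p.between_variance == pytest.approx(0.0, abs=1e-15)
        assert p.variance == pytest.approx(0.01)

    def test_two_imputation_arithmetic(self):
        p = pool_rubin([0.7, 0.8], [0.01, 0.01])
        assert p.estimate == pytest.approx(0.75)
        assert p.variance == pytest.approx(0.01 + 1.5 * 0.005)

    def test_order_invariance(self):
        a = pool_rubin([0.6, 0.7, 0.9], [0.01, 0.02, 0.03])
        b = pool_rubin([0.9, 0.6, 0.7], [0.03, 0.01, 0.02])
        assert a.estimate == pytest.approx(b.estimate)
        assert a.variance == pytest.approx(b.variance)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no estimates"):
            pool_rubin([], [])

    def test_concordance_pooling_back_transforms_into_bounds(self):
        from hivsurv.metrics import ConcordanceResult

        results = [
            ConcordanceResult(0.72, 0.02, None, None, 100),
            ConcordanceResult(0.78, 0.02, None, None, 100),
        ]
        pooled = pool_concordance(results)
        assert 0.72 < pooled.estimate < 0.78
        assert 0.0 < pooled.ci_low < pooled.estimate < pooled.ci_high < 1.0
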