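"""Discrimination, calibration and descriptive statistics for censored
survival data.

Everything here is implemented from first principles on numpy arrays:
the Kaplan–Meier product-limit and Nelson–Aalen cumulative-hazard
estimators, reverse-KM follow-up summaries, Harrell's overall concordance,
an IPCW time-dependent (truncated) concordance, Kaplan–Meier calibration
tables at fixed horizons, exact Poisson rate intervals, and Rubin's rules
for pooling multiply-imputed estimates.  Established packages (lifelines,
scikit-survival) are used in the test suite as independent oracles, never
here.

Conventions
-----------
* Scores are risk scores: higher = worse prognosis = earlier failure.
* Step functions are right-continuous; S(t) is the value *at* t.
* Calibration differences are observed − predicted survival, so a positive
  difference means the model underestimates survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "StepFunctionEstimate",
    "ConcordanceResult",
    "CalibrationTable",
    "RateEstimate",
    "FollowUpSummary",
    "RubinPooled",
    "kaplan_meier",
    "nelson_aalen",
    "reverse_km_median_followup",
    "harrells_c",
    "time_dependent_c",
    "calibration_table",
    "poisson_rate_ci",
    "pool_rubin",
    "pool_concordance",
]


@dataclass
class SurvivalSample:
    """Right-censored survival data with optional parallel risk scores."""

    times: np.ndarray
    events: np.ndarray
    scores: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.size and self.times.min() <= 0:
            raise ValueError("survival times must be positive")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.times.shape:
                raise ValueError("scores must parallel times")

    def __len__(self):
        return self.times.size


@dataclass
class StepFunctionEstimate:
    """Right-continuous step estimate over distinct event times."""

    times: np.ndarray      # ascending distinct event times
    values: np.ndarray     # estimate at (and after) each time
    at_risk: np.ndarray
    n_events: np.ndarray
    baseline: float        # value before the first event time (1 for KM, 0 for NA)

    def evaluate(self, t) -> np.ndarray | float:
        """Value at time(s) t (right-continuous lookup)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[self.baseline], self.values])
        out = padded[idx]
        return float(out) if np.isscalar(t) else out

    def evaluate_left(self, t) -> np.ndarray | float:
        """Left limit: value just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        padded = np.concatenate([[self.baseline], self.values])
        out = padded[idx]
        return float(out) if np.isscalar(t) else out


@dataclass
class ConcordanceResult:
    estimate: float
    standard_error: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_usable_pairs: float
    horizon: object = "overall"  # years, or "overall"


@dataclass
class CalibrationTable:
    """Per-bin predicted vs KM-observed survival at one horizon."""

    horizon: float
    table: pd.DataFrame  # columns: bin, n, mean_predicted, observed_km, difference
    mean_difference: float          # average of bin differences (default summary)
    mean_difference_patient: float  # n-weighted average
    max_difference: float           # signed difference of largest magnitude
    flagged_bins: list = field(default_factory=list)

    def to_csv(self, path, sep=","):
        self.table.to_csv(path, sep=sep, index=False)


@dataclass
class RateEstimate:
    events: int
    exposure: float  # person-years
    rate: float      # per 1000 person-years
    ci_low: float
    ci_high: float


@dataclass
class FollowUpSummary:
    median: Optional[float]
    q25: Optional[float]
    q75: Optional[float]
    defined: bool  # False when the reverse-KM curve never reaches the median


@dataclass
class RubinPooled:
    estimate: float
    variance: float          # total = within + (1 + 1/m)·between
    within_variance: float
    between_variance: float
    ci_low: float
    ci_high: float
    df: float
    m: int


# ---------------------------------------------------------------------------
# nonparametric estimators
# ---------------------------------------------------------------------------

def _check_nonempty(sample: SurvivalSample):
    if len(sample) == 0:
        raise ValueError("survival sample is empty")


def _risk_table(sample: SurvivalSample):
    """Distinct event times with events and at-risk counts."""
    order = np.argsort(sample.times, kind="mergesort")
    t = sample.times[order]
    e = sample.events[order]
    uniq, start = np.unique(t, return_index=True)
    # events per distinct time
    d = np.add.reduceat(e.astype(int), start)
    # at risk just before each distinct time: n - (# with time < t)
    n_at_risk = len(sample) - start
    keep = d > 0
    return uniq[keep], d[keep], n_at_risk[keep]


def kaplan_meier(sample: SurvivalSample) -> StepFunctionEstimate:
    """Product-limit survival estimate S(t) = Π (1 − d_j/n_j)."""
    _check_nonempty(sample)
    times, d, n = _risk_table(sample)
    values = np.cumprod(1.0 - d / n)
    return StepFunctionEstimate(times, values, n, d, baseline=1.0)


def nelson_aalen(sample: SurvivalSample) -> StepFunctionEstimate:
    """Cumulative hazard H(t) = Σ d_j/n_j over event times ≤ t."""
    _check_nonempty(sample)
    times, d, n = _risk_table(sample)
    values = np.cumsum(d / n)
    return StepFunctionEstimate(times, values, n, d, baseline=0.0)


def nelson_aalen_at_observed(sample: SurvivalSample) -> np.ndarray:
    """H(t_i) for every subject, for use as an imputation-model outcome."""
    na = nelson_aalen(SurvivalSample(sample.times, sample.events))
    return na.evaluate(sample.times)


def _km_quantile(km: StepFunctionEstimate, q: float) -> Optional[float]:
    """Smallest event time where the curve drops to <= q, else None."""
    hit = np.nonzero(km.values <= q)[0]
    if hit.size == 0:
        return None
    return float(km.times[hit[0]])


def reverse_km_median_followup(sample: SurvivalSample) -> FollowUpSummary:
    """Median (and IQR) follow-up by the reverse Kaplan–Meier method.

    Censoring is treated as the event and deaths as censored; the median
    follow-up is where the reverse-KM curve crosses 0.5.  When the curve
    never reaches a quantile (e.g. everyone died), that quantile is
    undefined and the result is flagged.
    """
    _check_nonempty(sample)
    flipped = SurvivalSample(sample.times, ~sample.events)
    if not flipped.events.any():
        return FollowUpSummary(None, None, None, defined=False)
    km = kaplan_meier(flipped)
    med = _km_quantile(km, 0.5)
    return FollowUpSummary(
        median=med,
        q25=_km_quantile(km, 0.75),
        q75=_km_quantile(km, 0.25),
        defined=med is not None,
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

_CHUNK = 512


def _concordance_counts(times, events, scores, per_subject: bool = False):
    """(weighted concordant, usable pairs) for Harrell's C.

    A pair is usable when the shorter time is an event, or the times are
    tied with exactly one event; tied event times are not usable.  Each
    usable pair is counted once with the (earlier) event subject as the
    case; tied scores contribute 1/2.

    With ``per_subject`` also returns each subject's share of the numerator
    and denominator (pairs it participates in), enabling exact leave-one-out
    recomputation.
    """
    n = times.size
    num = 0.0
    den = 0.0
    u = np.zeros(n) if per_subject else None
    v = np.zeros(n) if per_subject else None
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        ti = times[lo:hi, None]
        ei = events[lo:hi, None]
        si = scores[lo:hi, None]
        usable = ei & ((ti < times[None, :]) | ((ti == times[None, :]) & ~events[None, :]))
        contrib = ((si > scores[None, :]) + 0.5 * (si == scores[None, :])) * usable
        den += usable.sum()
        num += contrib.sum()
        if per_subject:
            u[lo:hi] += contrib.sum(axis=1)
            u += contrib.sum(axis=0)
            v[lo:hi] += usable.sum(axis=1)
            v += usable.sum(axis=0)
    if per_subject:
        return num, den, u, v
    return num, den


def harrells_c(
    sample: SurvivalSample,
    se_method: str | None = "jackknife",
    n_bootstrap: int = 200,
    seed: int | np.random.Generator | None = 0,
    level: float = 0.95,
) -> ConcordanceResult:
    """Harrell's overall concordance of risk scores with survival times.

    Over usable pairs, the fraction where the higher-risk subject fails
    first (score ties count 1/2).  The standard error is, by default, an
    exact delete-one jackknife (each leave-one-out estimate is recomputed
    exactly from per-subject pair totals in the same O(n²) pass);
    ``se_method="bootstrap"`` uses ``n_bootstrap`` nonparametric resamples
    instead, and ``None`` skips the standard error.  The confidence
    interval is normal, clipped to [0, 1].

    ``n_bootstrap=0`` is accepted as an alias for ``se_method=None``.
    """
    _check_nonempty(sample)
    if sample.scores is None:
        raise ValueError("sample has no scores")
    if n_bootstrap == 0 and se_method == "jackknife":
        se_method = None
    t, e, s = sample.times, sample.events, sample.scores

    se = ci_low = ci_high = None
    if se_method == "jackknife":
        num, den, u, v = _concordance_counts(t, e, s, per_subject=True)
        if den == 0:
            raise ValueError("no usable pairs (no events, or all event times tied)")
        est = num / den
        keep = (den - v) > 0
        loo = np.full(t.size, est)
        loo[keep] = (num - u[keep]) / (den - v[keep])
        n = t.size
        se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    else:
        num, den = _concordance_counts(t, e, s)
        if den == 0:
            raise ValueError("no usable pairs (no events, or all event times tied)")
        est = num / den
        if se_method == "bootstrap":
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            n = len(sample)
            reps = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, n, size=n)
                bn, bd = _concordance_counts(t[idx], e[idx], s[idx])
                if bd > 0:
                    reps.append(bn / bd)
            se = float(np.std(reps, ddof=1))
        elif se_method is not None:
            raise ValueError("se_method must be 'jackknife', 'bootstrap' or None")
    if se is not None:
        z = stats.norm.ppf(0.5 + level / 2)
        ci_low = max(0.0, est - z * se)
        ci_high = min(1.0, est + z * se)
    return ConcordanceResult(float(est), se, ci_low, ci_high, float(den), "overall")


def time_dependent_c(
    sample: SurvivalSample,
    horizon: float,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = 0,
    level: float = 0.95,
) -> ConcordanceResult:
    """IPCW truncated concordance at a fixed horizon.

    Cases are subjects with an observed event by the horizon; comparators
    are subjects still at risk (observed beyond the horizon).  Each pair is
    weighted by the inverse probability of remaining uncensored,
    1 / (G(T_case−)·G(horizon)), with G the Kaplan–Meier estimate of the
    censoring distribution.  With no censoring before the horizon all
    weights are 1 and this reduces to the plain truncated concordance.
    """
    _check_nonempty(sample)
    if sample.scores is None:
        raise ValueError("sample has no scores")
    if horizon > sample.times.max():
        raise ValueError(
            f"horizon {horizon} exceeds the longest observed follow-up {sample.times.max():.3g}"
        )
    t, e, s = sample.times, sample.events, sample.scores
    case = e & (t <= horizon)
    comp = t > horizon
    if not case.any():
        raise ValueError(f"no events observed by horizon {horizon}")
    if not comp.any():
        raise ValueError(f"no subjects at risk beyond horizon {horizon}")

    cens_km = kaplan_meier(SurvivalSample(t, ~e))
    g_case = cens_km.evaluate_left(t[case])
    g_tau = cens_km.evaluate(horizon)
    if g_tau <= 0 or np.any(g_case <= 0):
        raise ValueError("censoring survival is zero at a required time; IPCW weights undefined")

    w_case = 1.0 / (g_case * g_tau)  # pair weight; constant across comparators
    sc = s[case][:, None]
    so = s[comp][None, :]
    num = float((w_case[:, None] * ((sc > so) + 0.5 * (sc == so))).sum())
    den = float(w_case.sum() * comp.sum())
    est = num / den

    se = ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = len(sample)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                r = time_dependent_c(
                    SurvivalSample(t[idx], e[idx], s[idx]), horizon, n_bootstrap=0
                )
                reps.append(r.estimate)
            except ValueError:
                continue
        if len(reps) >= 2:
            se = float(np.std(reps, ddof=1))
            z = stats.norm.ppf(0.5 + level / 2)
            ci_low = max(0.0, est - z * se)
            ci_high = min(1.0, est + z * se)
    n_pairs = float(case.sum()) * float(comp.sum())
    return ConcordanceResult(float(est), se, ci_low, ci_high, n_pairs, horizon)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_table(
    predicted: Sequence[float],
    sample: SurvivalSample,
    horizon: float,
    n_bins: int = 10,
) -> CalibrationTable:
    """Compare mean predicted survival with KM-observed survival per bin.

    Subjects are binned by quantiles of predicted survival; within each bin
    the observed survival at the horizon is the bin's own Kaplan–Meier
    estimate.  difference = observed − predicted (positive = the model
    underestimates survival).  Bins whose KM curve has nobody at risk by
    the horizon are flagged.
    """
    _check_nonempty(sample)
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != sample.times.shape:
        raise ValueError("predicted must parallel the sample")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")

    # quantile bins; ties collapse bins rather than erroring
    edges = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_idx = np.searchsorted(np.unique(edges[1:-1]), pred, side="right")

    rows, flagged = [], []
    for b in np.unique(bin_idx):
        mask = bin_idx == b
        sub = SurvivalSample(sample.times[mask], sample.events[mask])
        km = kaplan_meier(sub) if sub.events.any() else None
        if sub.times.max() < horizon:
            observed = np.nan
            flagged.append(int(b))
        else:
            observed = km.evaluate(horizon) if km is not None else 1.0
        rows.append(
            {
                "bin": int(b),
                "n": int(mask.sum()),
                "mean_predicted": float(pred[mask].mean()),
                "observed_km": float(observed),
            }
        )
    table = pd.DataFrame(rows)
    table["difference"] = table["observed_km"] - table["mean_predicted"]
    ok = table["difference"].notna()
    mean_diff = float(table.loc[ok, "difference"].mean())
    mean_diff_patient = float(
        np.average(table.loc[ok, "difference"], weights=table.loc[ok, "n"])
    )
    diffs = table.loc[ok, "difference"].to_numpy()
    max_diff = float(diffs[np.argmax(np.abs(diffs))]) if diffs.size else np.nan
    return CalibrationTable(horizon, table, mean_diff, mean_diff_patient, max_diff, flagged)


# ---------------------------------------------------------------------------
# rates and pooling
# ---------------------------------------------------------------------------

def poisson_rate_ci(events: int, exposure: float, level: float = 0.95) -> RateEstimate:
    """Event rate per 1000 person-years with an exact Poisson interval.

    Bounds use the chi-square quantile form: lower = χ²(α/2, 2k)/2,
    upper = χ²(1−α/2, 2k+2)/2, scaled by exposure.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if events < 0:
        raise ValueError("events must be nonnegative")
    alpha = 1 - level
    lower = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * (events + 1)) / 2
    scale = 1000.0 / exposure
    return RateEstimate(
        events=int(events),
        exposure=float(exposure),
        rate=1000.0 * events / exposure,
        ci_low=lower * scale,
        ci_high=upper * scale,
    )


def pool_rubin(
    estimates: Sequence[float],
    variances: Sequence[float],
    level: float = 0.95,
) -> RubinPooled:
    """Rubin's rules on the working scale.

    Pooled estimate is the mean over imputations; total variance is
    within + (1 + 1/m)·between; the interval uses a t reference with
    Barnard–Rubin large-sample degrees of freedom (normal when the
    between-imputation variance is zero).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size == 0:
        raise ValueError("no estimates to pool")
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    m = q.size
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    if m > 1 and b > 0:
        r = (1 + 1 / m) * b / ubar if ubar > 0 else np.inf
        df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else float(m - 1)
        tq = stats.t.ppf(0.5 + level / 2, df)
    else:
        df = math.inf
        tq = stats.norm.ppf(0.5 + level / 2)
    half = tq * math.sqrt(total) if total > 0 else 0.0
    return RubinPooled(
        estimate=qbar,
        variance=total,
        within_variance=ubar,
        between_variance=b,
        ci_low=qbar - half,
        ci_high=qbar + half,
        df=float(df),
        m=int(m),
    )


def _logit(p):
    return math.log(p / (1 - p))


def _expit(x):
    return 1 / (1 + math.exp(-x))


def pool_concordance(results: Sequence[ConcordanceResult], level: float = 0.95) -> RubinPooled:
    """Pool per-imputation C-statistics on the logit scale (bounded in [0,1]).

    Variances transfer by the delta method, var_logit = var / (C(1−C))²;
    the pooled estimate and interval are back-transformed.
    """
    ests, variances = [], []
    for r in results:
        if r.standard_error is None:
            raise ValueError("concordance results need standard errors to pool")
        c = min(max(r.estimate, 1e-12), 1 - 1e-12)
        ests.append(_logit(c))
        variances.append(r.standard_error**2 / (c * (1 - c)) ** 2)
    pooled = pool_rubin(ests, variances, level=level)
    c = _expit(pooled.estimate)
    var_c = pooled.variance * (c * (1 - c)) ** 2
    return RubinPooled(
        estimate=c,
        variance=var_c,
        within_variance=pooled.within_variance * (c * (1 - c)) ** 2,
        between_variance=pooled.between_variance * (c * (1 - c)) ** 2,
        ci_low=_expit(pooled.ci_low),
        ci_high=_expit(pooled.ci_high),
        df=pooled.df,
        m=pooled.m,
    )
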