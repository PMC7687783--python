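"""End-to-end validation run: impute, score, validate, report.

`run_validation` reproduces the published analysis flow on any conforming
cohort table: log-transform labs → append the Nelson–Aalen outcome →
chained multiple imputation (m datasets) → per-imputation scoring and
metrics → Rubin pooling → calibration at 1/2/3 years and time-dependent
concordance over a horizon grid.  Sensitivity scenarios (complete-case and
the two viral-load assumptions) reuse the same machinery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, missing
from .metrics import SurvivalSample
from .model import ModelParameters, assign_risk_group, compute_risk_score, pi_from_frame, predict_survival_vector

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidationReport", "run_validation", "write_report", "read_report", "display_round"]

SCENARIOS = ("mi", "complete-case", "vl-low", "vl-reference")


@dataclass
class RunConfig:
    """Knobs of one validation run."""

    m: int = 50
    seed: int = 0
    n_bins: int = 10
    calibration_horizons: tuple = (1, 2, 3)
    td_c_horizons: tuple = (0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    scenario: str = "mi"
    c_se_method: str = "jackknife"  # standard error for the overall C ("jackknife"|"bootstrap")
    c_bootstrap: int = 200          # replicates when c_se_method == "bootstrap"
    mortality_horizons: tuple = (3, 5, 10, 15)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.m < 1:
            raise ValueError("m must be at least 1")


@dataclass
class ValidationReport:
    """Everything one validation run measured, JSON-serializable."""

    summary: dict                 # n, events, person-years, rate, follow-up, cumulative mortality
    concordance: dict             # pooled Harrell's C for original and extended scores
    time_dependent_c: dict        # horizon -> pooled estimate (and per-imputation spread)
    calibration: dict             # horizon -> averaged calibration table rows + summaries
    risk_groups: Optional[dict]
    pi_histogram: dict            # bin edges + counts of the per-subject mean PI
    provenance: dict              # seed, m, scenario, config/parameter hash

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


def _config_hash(params: ModelParameters, config: RunConfig) -> str:
    payload = json.dumps({"params": params.to_dict(), "config": asdict(config)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _complete_sets(cohort: pd.DataFrame, params: ModelParameters, config: RunConfig):
    """Produce the m completed datasets according to the scenario."""
    predictors = ["cd4", "hemoglobin", "viral_load_category"]
    any_missing = cohort[predictors].isna().any().any()
    scenario = config.scenario
    if scenario == "complete-case":
        kept = cohort.dropna(subset=predictors)
        logger.info("complete-case scenario: %d of %d rows retained", len(kept), len(cohort))
        return [kept], 1
    work = cohort
    if scenario == "vl-low":
        work = missing.scenario_vl_all_low(work)
    elif scenario == "vl-reference":
        work = missing.scenario_vl_reference_distribution(work, seed=config.seed + 7)
    if not work[predictors].isna().any().any():
        return [work], 1
    m = config.m
    logged = missing.log_transform_labs(work)
    imputed = missing.chained_imputation(logged, m=m, seed=config.seed)
    completed = [missing.inverse_log_transform_labs(c) for c in imputed.cohorts]
    return completed, m


def run_validation(
    cohort: pd.DataFrame,
    params: ModelParameters | None = None,
    config: RunConfig | None = None,
) -> ValidationReport:
    """Validate the model on one cohort table; see the module docstring."""
    params = params or ModelParameters()
    config = config or RunConfig()
    times = cohort["time"].to_numpy(float)
    events = cohort["event"].to_numpy(bool)
    base_sample = SurvivalSample(times, events)

    # ---- cohort description -------------------------------------------------
    rate = metrics.poisson_rate_ci(int(events.sum()), float(times.sum()))
    fu = metrics.reverse_km_median_followup(base_sample)
    km = metrics.kaplan_meier(base_sample)
    cum_mortality = {}
    for h in config.mortality_horizons:
        if h <= times.max():
            cum_mortality[str(h)] = 1.0 - float(km.evaluate(h))
        else:
            logger.info("cumulative-mortality horizon %s beyond observed follow-up; skipped", h)
    summary = {
        "n": int(len(cohort)),
        "events": int(events.sum()),
        "died_pct": 100.0 * float(events.mean()),
        "person_years": float(times.sum()),
        "mortality_rate_per_1000py": rate.rate,
        "mortality_rate_ci": [rate.ci_low, rate.ci_high],
        "median_followup_years": fu.median,
        "followup_iqr": [fu.q25, fu.q75],
        "cumulative_mortality": cum_mortality,
    }

    completed, m = _complete_sets(cohort, params, config)

    # ---- per-imputation metrics --------------------------------------------
    rng = np.random.default_rng(config.seed + 13)
    c_orig, c_ext = [], []
    td_by_h = {float(h): [] for h in config.td_c_horizons}
    calib_tables = {float(h): [] for h in config.calibration_horizons}
    pi_accum = np.zeros(0)
    for j, dfj in enumerate(completed):
        sj = SurvivalSample(
            dfj["time"].to_numpy(float), dfj["event"].to_numpy(bool)
        )
        pi = pi_from_frame(dfj, params, extended=False)
        pi_e = pi_from_frame(dfj, params, extended=True)
        pi_accum = pi if pi_accum.size == 0 else pi_accum + pi
        c_orig.append(
            metrics.harrells_c(
                SurvivalSample(sj.times, sj.events, pi),
                se_method=config.c_se_method, n_bootstrap=config.c_bootstrap, seed=rng,
            )
        )
        c_ext.append(
            metrics.harrells_c(
                SurvivalSample(sj.times, sj.events, pi_e),
                se_method=config.c_se_method, n_bootstrap=config.c_bootstrap, seed=rng,
            )
        )
        for h in td_by_h:
            if h >= sj.times.max():
                continue
            try:
                td_by_h[h].append(
                    metrics.time_dependent_c(SurvivalSample(sj.times, sj.events, pi), h).estimate
                )
            except ValueError as exc:
                logger.info("time-dependent C at %s y skipped: %s", h, exc)
        for h in calib_tables:
            pred = predict_survival_vector(pi, int(h) if float(h).is_integer() else h, params)
            calib_tables[h].append(metrics.calibration_table(pred, sj, h, config.n_bins))
    mean_pi = pi_accum / m

    # ---- pooling ------------------------------------------------------------
    def pool_c(results):
        if m == 1:
            r = results[0]
            return {
                "estimate": r.estimate,
                "ci": [r.ci_low, r.ci_high],
                "standard_error": r.standard_error,
                "m": 1,
            }
        pooled = metrics.pool_concordance(results)
        return {
            "estimate": pooled.estimate,
            "ci": [pooled.ci_low, pooled.ci_high],
            "between_variance": pooled.between_variance,
            "m": pooled.m,
        }

    concordance = {"original": pool_c(c_orig), "extended": pool_c(c_ext)}

    td_c = {}
    for h, vals in td_by_h.items():
        if not vals:
            continue
        td_c[str(h)] = {
            "estimate": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "m": len(vals),
        }

    calibration = {}
    for h, tabs in calib_tables.items():
        stacked = pd.concat([t.table for t in tabs])
        # bins are quantile-based, so sizes are near-identical across
        # imputations; the average is reported
        avg = stacked.groupby("bin", as_index=False).mean(numeric_only=True)
        calibration[str(h)] = {
            "bins": avg.to_dict(orient="records"),
            "mean_difference": float(np.mean([t.mean_difference for t in tabs])),
            "mean_difference_patient": float(np.mean([t.mean_difference_patient for t in tabs])),
            "max_difference": float(np.mean([t.max_difference for t in tabs])),
        }

    risk_groups = None
    if params.risk_group_cutoffs is not None:
        scores = np.array([compute_risk_score(v, params) for v in mean_pi])
        groups = pd.Series([assign_risk_group(s, params) for s in scores])
        counts = groups.value_counts()
        risk_groups = {g: int(counts.get(g, 0)) for g in ("low", "intermediate", "high")}

    hist_counts, hist_edges = np.histogram(mean_pi, bins=30)
    report = ValidationReport(
        summary=summary,
        concordance=concordance,
        time_dependent_c=td_c,
        calibration=calibration,
        risk_groups=risk_groups,
        pi_histogram={"edges": hist_edges.tolist(), "counts": hist_counts.tolist()},
        provenance={
            "seed": config.seed,
            "m": m,
            "scenario": config.scenario,
            "config_hash": _config_hash(params, config),
        },
    )
    return report


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def display_round(value: float, decimals: int = 2) -> str:
    """Display rounding used in tables: rates and percentages to 2 d.p."""
    return f"{value:.{decimals}f}"


def write_report(report: ValidationReport, path, format: str = "json") -> list:
    """Write a report as JSON (single file) or delimited tables (directory).

    Returns the list of files written.  JSON keeps full precision; the
    delimited form writes summary/calibration/time-dependent-C tables with
    display rounding applied to rates and percentages.
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(report.to_json())
        return [path]
    if format != "delimited":
        raise ValueError("format must be 'json' or 'delimited'")
    path.mkdir(parents=True, exist_ok=True)
    written = []
    s = report.summary
    summary_rows = [
        {"quantity": "n", "value": s["n"]},
        {"quantity": "events", "value": s["events"]},
        {"quantity": "died_pct", "value": display_round(s["died_pct"])},
        {"quantity": "person_years", "value": display_round(s["person_years"])},
        {"quantity": "mortality_rate_per_1000py", "value": display_round(s["mortality_rate_per_1000py"])},
        {"quantity": "mortality_rate_ci_low", "value": display_round(s["mortality_rate_ci"][0])},
        {"quantity": "mortality_rate_ci_high", "value": display_round(s["mortality_rate_ci"][1])},
    ]
    f = path / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(f, index=False)
    written.append(f)
    for h, cal in report.calibration.items():
        f = path / f"calibration_{h}y.csv"
        pd.DataFrame(cal["bins"]).to_csv(f, index=False)
        written.append(f)
    if report.time_dependent_c:
        f = path / "time_dependent_c.csv"
        rows = [{"horizon": h, **v} for h, v in report.time_dependent_c.items()]
        pd.DataFrame(rows).to_csv(f, index=False)
        written.append(f)
    return written


def read_report(path) -> ValidationReport:
    """Read back a JSON report written by :func:`write_report`."""
    d = json.loads(Path(path).read_text())
    return ValidationReport(**d)
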