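"""Reconstructed Wenzhou prognostic model for survival of people on ART.

The model is a Cox-type prognostic score built from three baseline
predictors — CD4 cell count (cells/µL), hemoglobin (g/L) and categorized
HIV viral load (copies/mL) — published as a nomogram.  This module encodes
the nomogram-derived coefficients, baseline survival probabilities and the
affine points mapping, plus an extended variant that adds age-band and
gender terms (coefficients taken from published hazard ratios, not
re-fitted).

Scoring is deliberately strict: records with a missing predictor raise
rather than being silently imputed — imputation is the job of
:mod:`hivsurv.missing`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

__all__ = [
    "VL_LT200",
    "VL_MID",
    "VL_GE1000",
    "PatientRecord",
    "ModelParameters",
    "PrognosticIndex",
    "MissingPredictorError",
    "UnsupportedHorizonError",
    "viral_load_category",
    "compute_prognostic_index",
    "compute_extended_pi",
    "predict_survival",
    "compute_risk_score",
    "invert_risk_score",
    "assign_risk_group",
]

# viral-load category labels (copies/mL bands [0,200), [200,1000), [1000,inf))
VL_LT200 = "LT200"
VL_MID = "MID"
VL_GE1000 = "GE1000"
_VL_CATEGORIES = (VL_LT200, VL_MID, VL_GE1000)


class MissingPredictorError(ValueError):
    """A predictor required for scoring is missing from the record."""

    def __init__(self, fieldname: str):
        self.fieldname = fieldname
        super().__init__(
            f"predictor {fieldname!r} is missing; scoring never imputes — "
            "complete the record first (see hivsurv.missing)"
        )


class UnsupportedHorizonError(ValueError):
    """Requested horizon has no baseline survival value."""

    def __init__(self, horizon, supported):
        self.horizon = horizon
        self.supported = tuple(sorted(supported))
        super().__init__(
            f"no baseline survival at horizon {horizon!r}; "
            f"supported horizons (years): {self.supported}"
        )


def viral_load_category(copies_per_ml: float) -> str:
    """Categorize a viral load in copies/mL.

    Bands are half-open: [0, 200) -> LT200, [200, 1000) -> MID,
    [1000, inf) -> GE1000; exactly 1000 copies/mL falls in GE1000.
    """
    if copies_per_ml < 0:
        raise ValueError("viral load cannot be negative")
    if copies_per_ml < 200:
        return VL_LT200
    if copies_per_ml < 1000:
        return VL_MID
    return VL_GE1000


@dataclass
class PatientRecord:
    """One subject: baseline predictors, demographics, follow-up.

    ``cd4`` in cells/µL, ``hemoglobin`` in g/L, ``viral_load_category`` one
    of {LT200, MID, GE1000}; ``time`` in years from ART initiation;
    ``event`` True if the subject died.  ``auxiliary`` carries optional
    covariates (CD8, platelets, ...) used only by the imputation model.
    """

    id: str
    cd4: Optional[float] = None
    hemoglobin: Optional[float] = None
    viral_load_category: Optional[str] = None
    age: Optional[float] = None
    gender: Optional[str] = None  # "male" | "female"
    time: Optional[float] = None
    event: Optional[bool] = None
    auxiliary: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.viral_load_category is not None and self.viral_load_category not in _VL_CATEGORIES:
            raise ValueError(
                f"viral_load_category must be one of {_VL_CATEGORIES}, got {self.viral_load_category!r}"
            )
        if self.time is not None and self.time <= 0:
            raise ValueError("follow-up time must be positive")


@dataclass(frozen=True)
class PrognosticIndex:
    """Linear predictor of the prognostic model."""

    value: float
    variant: str = "original"  # "original" | "extended"


@dataclass
class ModelParameters:
    """All published model constants at full printed precision.

    ``baseline_survival`` maps a horizon in years to S0(t), the survival of
    a subject with PI = 0; individual prediction is S0(t)^exp(PI).  The
    risk-group cutoffs were not published and therefore have no default:
    any run that needs risk groups must configure them explicitly.
    """

    coef_cd4: float = -0.005580907        # per cells/µL
    coef_hb: float = -0.005368102         # per g/L
    coef_vl_mid: float = 1.019669556      # 200–<1000 copies/mL vs <200
    coef_vl_high: float = 2.608969326     # ≥1000 copies/mL vs <200
    baseline_survival: dict = field(
        default_factory=lambda: {1: 0.980222074, 2: 0.972736744, 3: 0.964896148}
    )
    score_intercept: float = 108.3333333
    score_slope: float = 19.90914787
    ext_coef_age_mid: float = 0.2382292   # age in [40, 60)
    ext_coef_age_high: float = 0.5866749  # age >= 60
    ext_coef_female: float = -0.3566749
    risk_group_cutoffs: Optional[tuple] = None  # (low/intermediate, intermediate/high)

    def __post_init__(self):
        horizons = sorted(self.baseline_survival)
        values = [self.baseline_survival[h] for h in horizons]
        if any(not (0.0 < s < 1.0) for s in values):
            raise ValueError("baseline survival values must lie in (0, 1)")
        if any(b >= a for a, b in zip(values, values[1:])):
            pass  # strictly decreasing checked below
        if any(values[i + 1] >= values[i] for i in range(len(values) - 1)):
            raise ValueError("baseline survival must be strictly decreasing in horizon")
        if self.risk_group_cutoffs is not None:
            c1, c2 = self.risk_group_cutoffs
            if not c1 < c2:
                raise ValueError("risk-group cutoffs must be ascending")

    # -- flat key/value (de)serialization so alternative nomogram
    #    extractions can be swapped in from a JSON/YAML config -------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_survival"] = {str(k): v for k, v in self.baseline_survival.items()}
        if d["risk_group_cutoffs"] is not None:
            d["risk_group_cutoffs"] = list(d["risk_group_cutoffs"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        d = dict(d)
        if "baseline_survival" in d:
            d["baseline_survival"] = {float(k): float(v) for k, v in d["baseline_survival"].items()}
            # keep integer-valued horizons as ints so lookup by `3` works
            d["baseline_survival"] = {
                int(k) if float(k).is_integer() else k: v for k, v in d["baseline_survival"].items()
            }
        if d.get("risk_group_cutoffs") is not None:
            d["risk_group_cutoffs"] = tuple(d["risk_group_cutoffs"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _require(record: PatientRecord, fieldname: str):
    value = getattr(record, fieldname)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingPredictorError(fieldname)
    return value


def compute_prognostic_index(
    record: PatientRecord, params: ModelParameters | None = None
) -> PrognosticIndex:
    """Linear predictor: coef_cd4·CD4 + coef_hb·Hb + viral-load term."""
    params = params or ModelParameters()
    cd4 = _require(record, "cd4")
    hb = _require(record, "hemoglobin")
    vl = _require(record, "viral_load_category")
    vl_term = {VL_LT200: 0.0, VL_MID: params.coef_vl_mid, VL_GE1000: params.coef_vl_high}[vl]
    return PrognosticIndex(params.coef_cd4 * cd4 + params.coef_hb * hb + vl_term, "original")


def compute_extended_pi(
    record: PatientRecord, params: ModelParameters | None = None
) -> PrognosticIndex:
    """Original PI plus age-band ([40,60), [60,∞)) and female terms."""
    params = params or ModelParameters()
    base = compute_prognostic_index(record, params)
    age = _require(record, "age")
    gender = _require(record, "gender")
    extra = 0.0
    if 40 <= age < 60:
        extra += params.ext_coef_age_mid
    elif age >= 60:
        extra += params.ext_coef_age_high
    if gender == "female":
        extra += params.ext_coef_female
    elif gender != "male":
        raise ValueError(f"gender must be 'male' or 'female', got {gender!r}")
    return PrognosticIndex(base.value + extra, "extended")


def predict_survival(
    pi: PrognosticIndex | float, horizon: float, params: ModelParameters | None = None
) -> float:
    """Predicted survival S0(horizon)^exp(PI)."""
    params = params or ModelParameters()
    value = pi.value if isinstance(pi, PrognosticIndex) else float(pi)
    if horizon not in params.baseline_survival:
        raise UnsupportedHorizonError(horizon, params.baseline_survival)
    return params.baseline_survival[horizon] ** math.exp(value)


def compute_risk_score(
    pi: PrognosticIndex | float, params: ModelParameters | None = None
) -> float:
    """Nomogram points: intercept + slope·PI."""
    params = params or ModelParameters()
    value = pi.value if isinstance(pi, PrognosticIndex) else float(pi)
    if not math.isfinite(value):
        raise ValueError("prognostic index must be finite")
    return params.score_intercept + params.score_slope * value


def invert_risk_score(score: float, params: ModelParameters | None = None) -> float:
    """PI back from a risk score (the mapping is affine, hence invertible)."""
    params = params or ModelParameters()
    return (score - params.score_intercept) / params.score_slope


def pi_from_frame(frame, params: ModelParameters | None = None, extended: bool = False):
    """Vectorized prognostic index over a cohort table.

    ``frame`` needs columns cd4, hemoglobin, viral_load_category (and age,
    gender when ``extended``); rows must be complete — missing predictors
    raise, exactly as record-level scoring does.
    """
    import numpy as np

    params = params or ModelParameters()
    for col in ("cd4", "hemoglobin", "viral_load_category"):
        if frame[col].isna().any():
            raise MissingPredictorError(col)
    cd4 = frame["cd4"].to_numpy(dtype=float)
    hb = frame["hemoglobin"].to_numpy(dtype=float)
    vl = frame["viral_load_category"].to_numpy()
    pi = (
        params.coef_cd4 * cd4
        + params.coef_hb * hb
        + np.where(vl == VL_MID, params.coef_vl_mid, 0.0)
        + np.where(vl == VL_GE1000, params.coef_vl_high, 0.0)
    )
    if extended:
        for col in ("age", "gender"):
            if frame[col].isna().any():
                raise MissingPredictorError(col)
        age = frame["age"].to_numpy(dtype=float)
        female = frame["gender"].to_numpy() == "female"
        pi = (
            pi
            + np.where((age >= 40) & (age < 60), params.ext_coef_age_mid, 0.0)
            + np.where(age >= 60, params.ext_coef_age_high, 0.0)
            + np.where(female, params.ext_coef_female, 0.0)
        )
    return pi


def predict_survival_vector(pi_values, horizon: float, params: ModelParameters | None = None):
    """Vectorized S0(horizon)^exp(PI) for an array of prognostic indexes."""
    import numpy as np

    params = params or ModelParameters()
    if horizon not in params.baseline_survival:
        raise UnsupportedHorizonError(horizon, params.baseline_survival)
    return params.baseline_survival[horizon] ** np.exp(np.asarray(pi_values, dtype=float))


def assign_risk_group(score: float, params: ModelParameters) -> str:
    """Map a risk score to {low, intermediate, high} using configured cutoffs.

    Cutoffs are half-open: low if score < c1, intermediate if c1 <= score < c2,
    high otherwise.  Raises if cutoffs were never configured (the source
    nomogram's thresholds are not published).
    """
    if params.risk_group_cutoffs is None:
        raise ValueError(
            "risk_group_cutoffs are not configured; the published model does not "
            "print them — set ModelParameters.risk_group_cutoffs explicitly"
        )
    c1, c2 = params.risk_group_cutoffs
    if score < c1:
        return "low"
    if score < c2:
        return "intermediate"
    return "high"
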