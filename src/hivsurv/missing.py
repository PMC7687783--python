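"""Multiple imputation by chained equations and viral-load scenarios.

The imputation model follows the validation protocol: all predictors plus
auxiliary covariates, with the outcome represented by the Nelson–Aalen
cumulative-hazard estimate at each subject's observed time together with
the event indicator.  Laboratory values are log-transformed before entering
the model (they are positive and right-skewed).

Continuous variables are completed by predictive-mean matching (PMM)
against a Bayesian linear-regression draw; the categorical viral load by a
multinomial-logistic scoring draw.  Chained passes iterate a fixed number
of times; everything is seeded, and observed cells are never altered.

Two deterministic sensitivity scenarios for the (heavily missing) viral
load are also provided: set every missing value to the lowest category, or
draw missing categories from a reference distribution (e.g. the derivation
cohort's 78.7 / 3.0 / 18.3%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .metrics import SurvivalSample, nelson_aalen_at_observed
from .model import VL_GE1000, VL_LT200, VL_MID

logger = logging.getLogger(__name__)

__all__ = [
    "LAB_COLUMNS",
    "CategoryDistribution",
    "WENZHOU_VL_DISTRIBUTION",
    "ImputedCohortSet",
    "log_transform_labs",
    "inverse_log_transform_labs",
    "chained_imputation",
    "scenario_vl_all_low",
    "scenario_vl_reference_distribution",
]

# laboratory indexes: positive, right-skewed, log-transformed before modelling
LAB_COLUMNS = ("cd4", "hemoglobin", "cd8", "platelet", "wbc", "creatinine")

_VL_LEVELS = (VL_LT200, VL_MID, VL_GE1000)


@dataclass(frozen=True)
class CategoryDistribution:
    """Probabilities over the viral-load categories (LT200, MID, GE1000)."""

    lt200: float
    mid: float
    ge1000: float

    def __post_init__(self):
        p = self.as_array()
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("category probabilities must be nonnegative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.lt200, self.mid, self.ge1000], dtype=float)


#: viral-load distribution printed for the derivation cohort
WENZHOU_VL_DISTRIBUTION = CategoryDistribution(0.787, 0.030, 0.183)


@dataclass
class ImputedCohortSet:
    """m completed copies of one cohort plus imputation metadata."""

    m: int
    cohorts: list  # list[pd.DataFrame]
    seed: int
    methods: dict = field(default_factory=dict)  # variable -> method tag
    audit: Optional[pd.DataFrame] = None  # per-variable missing counts before/after

    def __post_init__(self):
        if self.m != len(self.cohorts):
            raise ValueError("m must equal the number of completed cohorts")


def log_transform_labs(cohort: pd.DataFrame, columns: Sequence[str] = LAB_COLUMNS) -> pd.DataFrame:
    """Natural log of the designated lab columns (missing cells pass through)."""
    out = cohort.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        if (vals <= 0).any():
            raise ValueError(f"column {col!r} has nonpositive values; cannot log-transform")
        out[col] = np.log(vals)
    return out


def inverse_log_transform_labs(
    cohort: pd.DataFrame, columns: Sequence[str] = LAB_COLUMNS
) -> pd.DataFrame:
    """Inverse of :func:`log_transform_labs`; round-trips to ~1e-12."""
    out = cohort.copy()
    for col in columns:
        if col in out.columns:
            out[col] = np.exp(out[col].astype(float))
    return out


# ---------------------------------------------------------------------------
# chained equations
# ---------------------------------------------------------------------------

def _feature_frame(df: pd.DataFrame, numeric_cols, has_vl, exclude: str) -> pd.DataFrame:
    """Numeric feature matrix for one target variable, from current values."""
    parts = {}
    for col in numeric_cols:
        if col != exclude:
            parts[col] = df[col].astype(float)
    if has_vl and exclude != "viral_load_category":
        parts["vl_mid"] = (df["viral_load_category"] == VL_MID).astype(float)
        parts["vl_high"] = (df["viral_load_category"] == VL_GE1000).astype(float)
    if "age" in df.columns:
        parts["age"] = df["age"].astype(float)
    if "gender" in df.columns:
        parts["female"] = (df["gender"] == "female").astype(float)
    if "era" in df.columns:
        era_codes = pd.Categorical(df["era"]).codes.astype(float)
        parts["era_idx"] = era_codes
    parts["na_cumhaz"] = df["_na_cumhaz"].astype(float)
    parts["event_ind"] = df["event"].astype(float)
    X = pd.DataFrame(parts, index=df.index)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        logger.warning("imputation: dropping degenerate constant predictor(s) %s", const)
        X = X.drop(columns=const)
    return X


def _bayes_linreg_draw(X: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draw (beta*) and least-squares fit (beta_hat) with intercept."""
    Xd = np.column_stack([np.ones(len(X)), X])
    n, p = Xd.shape
    xtx = Xd.T @ Xd + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(xtx, Xd.T @ y)
    resid = y - Xd @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(xtx)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_star, beta_hat


def _pmm_impute(X_obs, y_obs, X_mis, rng, donors: int) -> np.ndarray:
    """Predictive-mean matching: draw from the closest observed donors."""
    beta_star, beta_hat = _bayes_linreg_draw(X_obs, y_obs, rng)
    pred_obs = np.column_stack([np.ones(len(X_obs)), X_obs]) @ beta_hat
    pred_mis = np.column_stack([np.ones(len(X_mis)), X_mis]) @ beta_star
    k = min(donors, len(y_obs))
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(X_mis)), rng.integers(0, k, size=len(X_mis))]
    return y_obs[pick]


def _multinomial_impute(X_obs, y_obs_codes, X_mis, rng) -> np.ndarray:
    """Draw categories from a multinomial-logistic fit on observed rows."""
    classes = np.unique(y_obs_codes)
    if classes.size == 1:
        return np.full(len(X_mis), classes[0])
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X_obs, y_obs_codes)
    probs = clf.predict_proba(X_mis)
    cum = probs.cumsum(axis=1)
    u = rng.uniform(size=len(X_mis))[:, None]
    draw_idx = (u > cum).sum(axis=1)
    return clf.classes_[draw_idx]


def chained_imputation(
    cohort: pd.DataFrame,
    m: int = 50,
    seed: int = 0,
    iterations: int = 10,
    donor_pool: int = 5,
) -> ImputedCohortSet:
    """m completed copies of the cohort via chained equations.

    The Nelson–Aalen cumulative hazard at each subject's observed time and
    the event indicator are appended to the predictor set before imputation.
    Continuous variables use PMM (donor pool of ``donor_pool``); the
    viral-load category uses a multinomial-logistic scoring draw.  Fully
    seeded: the same seed yields an identical result.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    work = cohort.copy()
    sample = SurvivalSample(work["time"].to_numpy(float), work["event"].to_numpy(bool))
    work["_na_cumhaz"] = nelson_aalen_at_observed(sample)

    numeric_targets = [c for c in LAB_COLUMNS if c in work.columns]
    skipped = [c for c in LAB_COLUMNS if c not in work.columns]
    if skipped:
        logger.info("imputation: columns absent from the schema, skipped: %s", skipped)
    has_vl = "viral_load_category" in work.columns

    targets = []
    for col in numeric_targets:
        n_miss = int(work[col].isna().sum())
        if n_miss:
            if work[col].notna().sum() == 0:
                raise ValueError(f"variable {col!r} has no observed values to learn from")
            targets.append((col, "pmm", n_miss))
    if has_vl and work["viral_load_category"].isna().any():
        if work["viral_load_category"].notna().sum() == 0:
            raise ValueError("viral_load_category has no observed values to learn from")
        targets.append(("viral_load_category", "multinomial", int(work["viral_load_category"].isna().sum())))

    methods = {name: method for name, method, _ in targets}
    audit = pd.DataFrame(
        [{"variable": name, "missing_before": n, "missing_after": 0} for name, _, n in targets]
    )

    if not targets:  # nothing to do: m identical copies
        completed = [cohort.copy() for _ in range(m)]
        return ImputedCohortSet(m, completed, seed, methods, audit)

    master_rng = np.random.default_rng(seed)
    child_seeds = master_rng.integers(0, 2**31 - 1, size=m)
    completed = []
    for j in range(m):
        rng = np.random.default_rng(child_seeds[j])
        df = work.copy()
        # initialize every hole with a random observed value
        for name, method, _ in targets:
            miss = df[name].isna()
            obs = df.loc[~miss, name].to_numpy()
            df.loc[miss, name] = rng.choice(obs, size=int(miss.sum()), replace=True)
        for _ in range(iterations):
            for name, method, _ in targets:
                miss = work[name].isna().to_numpy()  # original missingness pattern
                X = _feature_frame(df, numeric_targets, has_vl, exclude=name)
                X_obs, X_mis = X.to_numpy(float)[~miss], X.to_numpy(float)[miss]
                if method == "pmm":
                    y_obs = work.loc[~miss, name].to_numpy(float)
                    df.loc[miss, name] = _pmm_impute(X_obs, y_obs, X_mis, rng, donor_pool)
                else:
                    codes = pd.Categorical(
                        work.loc[~miss, name], categories=_VL_LEVELS
                    ).codes
                    drawn = _multinomial_impute(X_obs, codes, X_mis, rng)
                    df.loc[miss, name] = np.asarray(_VL_LEVELS, dtype=object)[drawn]
        out = df.drop(columns=["_na_cumhaz"])
        completed.append(out)
    return ImputedCohortSet(m, completed, int(seed), methods, audit)


# ---------------------------------------------------------------------------
# viral-load sensitivity scenarios
# ---------------------------------------------------------------------------

def scenario_vl_all_low(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assume every missing viral load is < 200 copies/mL."""
    out = cohort.copy()
    miss = out["viral_load_category"].isna()
    if miss.any():
        out["viral_load_category"] = out["viral_load_category"].astype(object)
        out.loc[miss, "viral_load_category"] = VL_LT200
    return out


def scenario_vl_reference_distribution(
    cohort: pd.DataFrame,
    dist: CategoryDistribution = WENZHOU_VL_DISTRIBUTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw missing viral-load categories from a reference distribution.

    The empirical distribution of the filled-in cells converges to ``dist``
    as their number grows; observed cells are never altered.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    miss = out["viral_load_category"].isna().to_numpy()
    n_miss = int(miss.sum())
    if n_miss:
        out["viral_load_category"] = out["viral_load_category"].astype(object)
        draws = rng.choice(3, size=n_miss, p=dist.as_array())
        out.loc[miss, "viral_load_category"] = np.asarray(_VL_LEVELS, dtype=object)[draws]
    return out
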