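"""Read a patient-level cohort file and apply the inclusion criteria.

Expected schema: one row per patient, delimited text, missing cells empty.

=====================  =========================================================
column                 meaning
=====================  =========================================================
id                     opaque identifier (generated when absent)
cd4                    baseline CD4 count, cells/µL
hemoglobin             baseline hemoglobin, g/L
viral_load_category    LT200 | MID | GE1000 (derived from viral_load_copies
                       by the bands [0,200), [200,1000), [1000,∞) when absent)
viral_load_copies      baseline HIV viral load, copies/mL (optional)
age                    years at ART initiation
gender                 male | female
time                   follow-up, years from ART initiation (> 0)
event                  1 = died, 0 = censored
n_art_drugs            drugs in the initial regimen (inclusion: ≥ 3)
n_followup_records     follow-up visits on file (inclusion: ≥ 1)
weight, height         kg, m (optional; bmi = weight/height² derived)
era, cd8, platelet,    optional auxiliary covariates for the imputation model
wbc, creatinine
=====================  =========================================================

Inclusion criteria (combination ART of ≥3 drugs, age > 15, at least one
follow-up record) are applied only when their columns are present, and each
exclusion is logged with its reason and row number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import viral_load_category

__all__ = ["IngestResult", "ingest_cohort"]

_KNOWN_COLUMNS = {
    "id", "cd4", "hemoglobin", "viral_load_category", "viral_load_copies",
    "age", "gender", "time", "event", "n_art_drugs", "n_followup_records",
    "weight", "height", "bmi", "era", "cd8", "platelet", "wbc", "creatinine",
}
_REQUIRED = ("age", "gender", "time", "event")


@dataclass
class IngestResult:
    data: pd.DataFrame
    exclusions: pd.DataFrame  # columns: row, id, reason
    n_input: int

    @property
    def n_retained(self) -> int:
        return len(self.data)


def ingest_cohort(path, sep: str = ",") -> IngestResult:
    """Parse, validate and filter a cohort file."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file {path} lacks required column(s): {missing_cols}")

    # schema validation with row attribution (header = row 1)
    bad_time = df.index[df["time"].isna() | (df["time"] <= 0)]
    if len(bad_time):
        rows = [int(i) + 2 for i in bad_time[:10]]
        raise ValueError(f"nonpositive or missing follow-up time at file row(s) {rows}")
    bad_gender = df.index[~df["gender"].isin(["male", "female"])]
    if len(bad_gender):
        rows = [int(i) + 2 for i in bad_gender[:10]]
        raise ValueError(f"gender must be male/female at file row(s) {rows}")

    if "id" not in df.columns:
        df = df.copy()
        df.insert(0, "id", [f"P{i:06d}" for i in range(len(df))])

    # derived fields
    if "viral_load_category" not in df.columns and "viral_load_copies" in df.columns:
        copies = df["viral_load_copies"]
        df["viral_load_category"] = [
            viral_load_category(v) if pd.notna(v) else np.nan for v in copies
        ]
    if "bmi" not in df.columns and {"weight", "height"} <= set(df.columns):
        df["bmi"] = df["weight"] / df["height"] ** 2

    exclusions = []
    keep = df.index
    if "n_art_drugs" in df.columns:
        mask = df.loc[keep, "n_art_drugs"] < 3
        exclusions += [
            {"row": int(i) + 2, "id": df.at[i, "id"], "reason": "ART regimen with fewer than 3 drugs"}
            for i in keep[mask]
        ]
        keep = keep[~mask]
    mask = df.loc[keep, "age"] <= 15
    exclusions += [
        {"row": int(i) + 2, "id": df.at[i, "id"], "reason": "age 15 or younger"}
        for i in keep[mask]
    ]
    keep = keep[~mask]
    if "n_followup_records" in df.columns:
        mask = df.loc[keep, "n_followup_records"] < 1
        exclusions += [
            {"row": int(i) + 2, "id": df.at[i, "id"], "reason": "no follow-up record"}
            for i in keep[mask]
        ]
        keep = keep[~mask]

    data = df.loc[keep].reset_index(drop=True)
    exc = pd.DataFrame(exclusions, columns=["row", "id", "reason"])
    return IngestResult(data=data, exclusions=exc, n_input=len(df))
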