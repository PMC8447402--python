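"""Cohort container and patient-record schema.

A cohort is one row per patient: binary and categorical clinical covariates,
progression-free survival time in months (continuous) and an event flag
(True = progression observed, False = right-censored).  The on-disk format
is a plain CSV with booleans as 0/1 and categorical levels as lowercase
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

# Binary covariates (stored as bool, serialized as 0/1).
BINARY_COLUMNS = [
    "age_ge45",
    "hepatitis",
    "afp_ge400",
    "size_ge50mm",
    "number_ge4",
    "cirrhosis",
    "combined_tace",
]

# Categorical covariates with their admissible levels.
CATEGORICAL_LEVELS = {
    "sex": ["male", "female"],
    "treatment": ["surgery", "ablation"],
    "differentiation": ["well", "moderate", "poor", "unknown"],
    "satellite": ["no", "yes", "unknown"],
    "venous_invasion": ["no", "yes", "unknown"],
    "perineural_invasion": ["no", "yes", "unknown"],
    "capsule_invasion": ["no", "yes", "unknown"],
}

COVARIATE_COLUMNS = BINARY_COLUMNS + list(CATEGORICAL_LEVELS)

COLUMNS = ["patient_id"] + COVARIATE_COLUMNS + ["pfs_months", "event"]


@dataclass
class Cohort:
    """A set of patient records plus a free-text label (train/validation/full)."""

    data: pd.DataFrame
    label: str = "cohort"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        if self.data["patient_id"].duplicated().any():
            raise ValueError("patient_id values must be unique within a cohort")
        if (self.data["pfs_months"] <= 0).any():
            raise ValueError("pfs_months must be strictly positive")
        for col, levels in CATEGORICAL_LEVELS.items():
            bad = set(self.data[col].unique()) - set(levels)
            if bad:
                raise ValueError(f"column {col!r} has invalid levels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def event_proportion(self) -> float:
        return float(self.data["event"].mean())

    def covariates(self) -> pd.DataFrame:
        """Covariate block only, in canonical column order."""
        return self.data[COVARIATE_COLUMNS]

    def covariates_onehot(self) -> pd.DataFrame:
        """Numeric design matrix: binaries as 0/1, categoricals one-hot.

        'unknown' levels are kept as their own indicator column, never imputed.
        All levels are expanded (no reference-level drop) so every covariate
        enters downstream models, mirroring a no-variable-selection fit.
        """
        parts = [self.data[BINARY_COLUMNS].astype(float)]
        for col, levels in CATEGORICAL_LEVELS.items():
            cat = pd.Categorical(self.data[col], categories=levels)
            parts.append(pd.get_dummies(cat, prefix=col).astype(float))
        out = pd.concat(parts, axis=1)
        out.index = self.data.index
        return out


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Serialize to CSV: booleans as 0/1, categoricals lowercase, months as decimals."""
    df = cohort.data.copy()
    for col in BINARY_COLUMNS + ["event"]:
        df[col] = df[col].astype(int)
    df[COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path: str | Path, label: str | None = None) -> Cohort:
    df = pd.read_csv(path)
    for col in BINARY_COLUMNS + ["event"]:
        df[col] = df[col].astype(bool)
    df["pfs_months"] = df["pfs_months"].astype(float)
    return Cohort(df, label=label or Path(path).stem)
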