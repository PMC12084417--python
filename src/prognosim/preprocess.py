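"""Cohort cleaning, imputation, collinearity pruning and time discretization.

The cleaning rules mirror standard survival-cohort preparation: deaths
from causes other than the cancer are removed (their survival time says
nothing about disease-specific prognosis), identifiers are kept as row
keys but never as features, ordinal/categorical gaps are filled with the
column mode and continuous gaps with the column mean, features whose
absolute Pearson correlation with an already-retained feature exceeds a
threshold (default 0.6) are dropped — with a composite prognostic index
preferred over its components — and right-skewed age/tumor-size columns
are replaced by their natural logarithms.

Time discretization turns the survival pair (months, event) into one
binary classification problem per horizon t ∈ {2..9} years: y=1 for a
cancer death within t years, y=0 for survival beyond t years, and
patients censored before the horizon are excluded (their status at t is
unknown, so labeling them survivors would bias the classifier).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SubsetLabels",
    "REQUIRED_COLUMNS",
    "clean",
    "impute",
    "drop_collinear",
    "log_transform",
    "discretize_time",
    "nottingham_index",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "overallsurvivalmonths",
    "overall_survival",
    "deathfromcancer",
)

#: survival/outcome columns that are never treated as model features
OUTCOME_COLUMNS = ("overallsurvivalmonths", "overall_survival", "deathfromcancer")

LOG_RENAMES = {"ageatdiagnosis": "log_age", "tumor_size": "log_tumor_size"}

#: retained in preference to its components during collinearity pruning
COMPOSITE_PRIORITY = ("nottingham_prognostic_index",)


@dataclass(frozen=True)
class SubsetLabels:
    """Binary labels for one horizon: y=1 ⇔ cancer death within t years."""

    t: int
    patient_ids: tuple
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.patient_ids) != len(self.y):
            raise ValueError("patient_ids and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.y)


def clean(table: pd.DataFrame) -> pd.DataFrame:
    """Drop other-cause deaths; demote patient_id to a row key.

    Also merges duplicated cancer-type columns (a detailed subtype column
    is redundant with the coarse one for modelling) when both are present.
    Idempotent.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns and table.index.name != col:
            raise KeyError(f"missing required column: {col}")
    out = table.copy()
    if out.index.name != "patient_id":
        out = out.set_index("patient_id")
    died = out["overall_survival"].astype(int) == 1
    other = out["deathfromcancer"].astype(str).str.lower().isin(("no", "died of other causes"))
    out = out.loc[~(died & other)]
    if "cancer_type" in out.columns and "cancer_type_detailed" in out.columns:
        out = out.drop(columns=["cancer_type_detailed"])
    return out


def impute(table: pd.DataFrame) -> pd.DataFrame:
    """Mode-fill categorical/ordinal columns, mean-fill continuous ones."""
    out = table.copy()
    for col in out.columns:
        series = out[col]
        if not series.isna().any():
            continue
        if series.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.fillna(series.mean())
        else:
            out[col] = series.fillna(series.mode(dropna=True).iloc[0])
    return out


def drop_collinear(
    table: pd.DataFrame, threshold: float = 0.6
) -> Tuple[pd.DataFrame, List[str]]:
    """Greedy pruning of numeric features correlated above the threshold.

    Columns are visited in order (composite prognostic indices first, so
    the composite survives and its components are dropped); a column whose
    absolute Pearson correlation with any already-retained column exceeds
    the threshold is removed. Outcome columns are never candidates.
    """
    numeric = [
        c
        for c in table.columns
        if c not in OUTCOME_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not numeric:
        raise ValueError("need at least one numeric feature column")
    order = [c for c in COMPOSITE_PRIORITY if c in numeric] + [
        c for c in numeric if c not in COMPOSITE_PRIORITY
    ]
    corr = table[numeric].corr().abs()
    kept: List[str] = []
    dropped: List[str] = []
    for col in order:
        if any(corr.loc[col, k] > threshold for k in kept):
            dropped.append(col)
        else:
            kept.append(col)
    return table.drop(columns=dropped), dropped


def log_transform(
    table: pd.DataFrame, columns: Sequence[str] = ("ageatdiagnosis", "tumor_size")
) -> pd.DataFrame:
    """Replace right-skewed columns by their natural logs (log_age, …)."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"missing column: {col}")
        vals = out[col].astype(float)
        if (vals <= 0).any():
            raise ValueError(f"column {col!r} has nonpositive values; cannot log-transform")
        out[col] = np.log(vals)
    return out.rename(columns={c: LOG_RENAMES.get(c, f"log_{c}") for c in columns})


def discretize_time(
    table: pd.DataFrame, thresholds: Iterable[int] = range(2, 10)
) -> List[SubsetLabels]:
    """One binary outcome per horizon t (years).

    y=1: died of disease within 12·t months. y=0: survived (or was still
    under follow-up) beyond 12·t months, whatever the later status.
    Excluded: censored at or before the horizon — outcome unknowable.
    """
    months = table["overallsurvivalmonths"].astype(float).to_numpy()
    if np.any(months < 0):
        raise ValueError("survival months must be nonnegative")
    event = table["overall_survival"].astype(int).to_numpy()
    ids = np.asarray(table.index if table.index.name == "patient_id" else table["patient_id"])
    out = []
    for t in thresholds:
        horizon = 12.0 * t
        died_by_t = (event == 1) & (months <= horizon)
        beyond = months > horizon
        include = died_by_t | beyond
        y = died_by_t[include].astype(int)
        out.append(SubsetLabels(int(t), tuple(ids[include]), y))
    return out


def nottingham_index(table: pd.DataFrame) -> pd.Series:
    """Composite prognostic index from tumor size, nodal stage and grade.

    0.2·size(cm) + nodal stage (1: 0 nodes, 2: 1–3, 3: ≥4) + grade. The
    size column is in mm, as imaging reports it.
    """
    size_cm = table["tumor_size"].astype(float) / 10.0
    nodes = table["lymph_nodes_examined_positive"].astype(float)
    node_stage = np.where(nodes == 0, 1, np.where(nodes <= 3, 2, 3))
    grade = table["neoplasm_histologic_grade"].astype(float)
    return pd.Series(
        0.2 * size_cm + node_stage + grade, index=table.index, name="nottingham_prognostic_index"
    )
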