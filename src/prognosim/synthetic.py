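"""Synthetic breast-cancer cohorts, expression profiles and trajectories.

Real cohorts with this schema (clinical covariates + survival months +
event indicator + optional per-gene expression) require controlled-access
downloads; this module emulates one so that every other part of the
package is exercisable offline. The generator reproduces the qualitative
features the downstream methods rely on:

* right-skewed age and tumor size (both are log-transformed downstream
  precisely because of that skew);
* count-valued mutation burden and positive lymph nodes;
* ordinal grade (1–3) and stage (1–4), binary receptor/therapy flags;
* survival times from an exponential proportional-hazards law whose
  hazard rises with mutation count, nodal involvement, tumor size,
  grade and age, with independent censoring;
* optional log-normal expression columns tied to mutation burden through
  a shared latent factor, so low-rank compression has structure to find.

Marginal shapes are the package's own choices (no public parameter set
exists for them); defaults are tuned to resemble published summaries of
large breast-cancer registries (median age ≈ 61 y, median tumor ≈ 22 mm,
mean nodal count ≈ 2, mean mutation count ≈ 5.5, median survival ≈ 10 y).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .abm import logistic_trajectory

__all__ = [
    "CohortSpec",
    "DEFAULT_HAZARD_WEIGHTS",
    "SCHEMA_COLUMNS",
    "generate_cohort",
    "inject_missingness",
    "generate_trajectory",
    "read_cohort",
    "write_cohort",
]

#: per-standard-deviation log-hazard increments of the survival generator
DEFAULT_HAZARD_WEIGHTS: Dict[str, float] = {
    "mutation_count": 0.40,
    "lymph_nodes_examined_positive": 0.30,
    "tumor_size": 0.25,
    "neoplasm_histologic_grade": 0.30,
    "ageatdiagnosis": 0.15,
}

SCHEMA_COLUMNS = [
    "patient_id",
    "ageatdiagnosis",
    "tumor_size",
    "tumor_stage",
    "neoplasm_histologic_grade",
    "lymph_nodes_examined_positive",
    "mutation_count",
    "cellularity",
    "chemotherapy",
    "hormone_therapy",
    "radio_therapy",
    "er_status",
    "pr_status",
    "her2_status",
    "overallsurvivalmonths",
    "overall_survival",
    "deathfromcancer",
]

_HAZARD_FEATURES = tuple(DEFAULT_HAZARD_WEIGHTS)

#: baseline hazard per month: median survival 120 months at covariate means
_BASELINE_HAZARD = np.log(2.0) / 120.0


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort; identical spec+seed ⇒ identical table."""

    n_patients: int = 500
    n_genes: int = 0
    seed: int = 0
    hazard_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_WEIGHTS)
    )
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    other_cause_death_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        for name, val in (
            ("censor_rate", self.censor_rate),
            ("other_cause_death_frac", self.other_cause_death_frac),
        ):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for col, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {col} must lie in [0, 1]")
        unknown = set(self.hazard_weights) - set(_HAZARD_FEATURES)
        if unknown:
            raise ValueError(f"unknown hazard features: {sorted(unknown)}")

    # YAML round trip -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["hazard_weights"] = dict(self.hazard_weights)
        doc["missing_rates"] = dict(self.missing_rates)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full cohort table from the spec.

    Covariates first, then survival: the per-patient hazard is
    λ_i = λ₀·exp(Σ_f w_f·z_f,i) on within-cohort z-scored features, event
    times are exponential, and each patient is independently censored with
    probability ``censor_rate`` at a uniform point of their follow-up.
    """
    n = spec.n_patients
    rng = np.random.default_rng(spec.seed)
    expr_cols = [f"E_{g + 1}" for g in range(spec.n_genes)]

    if n == 0:
        return pd.DataFrame(columns=SCHEMA_COLUMNS + expr_cols)

    age = 25.0 + rng.gamma(shape=6.0, scale=6.0, size=n)
    tumor_size = rng.lognormal(mean=3.1, sigma=0.55, size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.22, 0.48, 0.25, 0.05])
    grade = rng.choice([1, 2, 3], size=n, p=[0.12, 0.42, 0.46])
    nodes = rng.negative_binomial(n=0.9, p=0.31, size=n)

    # shared latent factor couples mutation burden and expression
    latent = rng.standard_normal(n)
    mutation = rng.poisson(np.exp(np.log(5.5) + 0.35 * latent - 0.35**2 / 2.0))

    cellularity = rng.choice(["low", "moderate", "high"], size=n, p=[0.2, 0.35, 0.45])
    chemo = rng.binomial(1, 0.25, size=n)
    hormone = rng.binomial(1, 0.60, size=n)
    radio = rng.binomial(1, 0.60, size=n)
    er = rng.binomial(1, 0.75, size=n)
    pr = rng.binomial(1, 0.50, size=n)
    her2 = rng.binomial(1, 0.12, size=n)

    feats = {
        "mutation_count": mutation.astype(float),
        "lymph_nodes_examined_positive": nodes.astype(float),
        "tumor_size": tumor_size,
        "neoplasm_histologic_grade": grade.astype(float),
        "ageatdiagnosis": age,
    }
    lin = np.zeros(n)
    for name, w in spec.hazard_weights.items():
        lin += w * _zscore(feats[name])
    hazard = _BASELINE_HAZARD * np.exp(lin)
    T_event = rng.exponential(1.0 / hazard)

    censored = rng.random(n) < spec.censor_rate
    follow_frac = rng.uniform(0.0, 1.0, size=n)
    months = np.where(censored, T_event * follow_frac, T_event)
    event = (~censored).astype(int)

    other_cause = (event == 1) & (rng.random(n) < spec.other_cause_death_frac)
    deathfromcancer = np.where(event == 1, np.where(other_cause, "no", "yes"), "no")

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "ageatdiagnosis": age,
            "tumor_size": tumor_size,
            "tumor_stage": stage,
            "neoplasm_histologic_grade": grade,
            "lymph_nodes_examined_positive": nodes,
            "mutation_count": mutation,
            "cellularity": cellularity,
            "chemotherapy": chemo,
            "hormone_therapy": hormone,
            "radio_therapy": radio,
            "er_status": er,
            "pr_status": pr,
            "her2_status": her2,
            "overallsurvivalmonths": months,
            "overall_survival": event,
            "deathfromcancer": deathfromcancer,
        }
    )

    if spec.n_genes:
        loadings = np.where(np.arange(spec.n_genes) % 2 == 0, 0.8, 0.0)
        noise = rng.standard_normal((n, spec.n_genes))
        logE = 1.0 + latent[:, None] * loadings[None, :] + 0.4 * noise
        table[expr_cols] = np.exp(logE)

    if spec.missing_rates:
        table = inject_missingness(table, spec.missing_rates, seed=spec.seed + 1)
    return table


def inject_missingness(
    table: pd.DataFrame, rates: Mapping[str, float], seed: int = 0
) -> pd.DataFrame:
    """Blank cells completely at random, per-column, at the given rates."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        if col not in out.columns:
            raise KeyError(f"unknown column: {col}")
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missing rate for {col} must lie in [0, 1]")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iub":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def generate_trajectory(
    r: float,
    K: float,
    N0: float,
    d: float = 0.0,
    noise_sd: float = 0.0,
    T: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Noisy observation of a logistic-minus-death growth curve.

    The underlying path is the exact solution of
    dN/dt = r·N·(1 − N/K) − d·N sampled at unit times 0..T; Gaussian
    observation noise (sd ``noise_sd``) is added on top. ``noise_sd=0``
    returns the deterministic path itself.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if N0 < 0:
        raise ValueError("N0 must be nonnegative")
    if T < 0:
        raise ValueError("T must be nonnegative")
    times = np.arange(T + 1, dtype=float)
    path = logistic_trajectory(r, K, N0, d, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        path = path + rng.normal(0.0, noise_sd, size=path.shape)
    return path


# --------------------------------------------------------------------------
# CSV IO
# --------------------------------------------------------------------------


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
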