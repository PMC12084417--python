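"""Map patient gene-expression and clinical data onto agent parameters.

The tumor simulator is patient-specific: every cancer-cell agent starts
with the patient's measured expression vector, the growth term of the size
update is driven by a weighted sum of growth-gene expression, and the
initial agent count is the measured tumor volume divided by an average
cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthGeneSet",
    "init_agent_expression",
    "growth_signal",
    "interaction_term",
    "initial_cell_count",
]


@dataclass(frozen=True)
class GrowthGeneSet:
    """Indices into the expression vector of cell-cycle genes, with weights.

    ``growth_signal`` computes E_growth = Σ_j W_j · E_{gene_indices[j]},
    the scalar that scales the proliferative term of the size update.
    """

    gene_indices: tuple = field(default_factory=tuple)
    W: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_indices", tuple(int(i) for i in self.gene_indices))
        object.__setattr__(self, "W", tuple(float(w) for w in self.W))
        if len(self.gene_indices) != len(self.W):
            raise ValueError("gene_indices and W must have equal length")
        if not all(math.isfinite(w) for w in self.W):
            raise ValueError("weights must be finite")


def init_agent_expression(patient_E: Sequence[float], n_genes: int | None = None) -> np.ndarray:
    """Initial agent expression M_i(0) = E_i from the patient sample.

    A direct copy: the simulated tumor starts from the patient's measured
    profile. Negative entries or a length mismatch with the configured
    number of genes are rejected.
    """
    E = np.asarray(patient_E, dtype=float)
    if E.ndim != 1:
        raise ValueError("patient expression must be a 1-D vector")
    if E.size and np.any(E < 0):
        raise ValueError("expression levels must be nonnegative")
    if n_genes is not None and E.size != n_genes:
        raise ValueError(f"expected {n_genes} genes, got {E.size}")
    return E.copy()


def growth_signal(E: Sequence[float], genes: GrowthGeneSet) -> float:
    """Weighted growth-gene expression E_growth = Σ W_j·E_j.

    Linear in E by construction; an empty gene set contributes 0.
    """
    E = np.asarray(E, dtype=float)
    if not genes.gene_indices:
        return 0.0
    idx = np.asarray(genes.gene_indices)
    if idx.size and (idx.min() < 0 or idx.max() >= E.shape[-1]):
        raise IndexError("gene index out of range")
    w = np.asarray(genes.W)
    return float(E[..., idx] @ w) if E.ndim == 1 else E[..., idx] @ w


def interaction_term(k: float, A: float, sign: int = -1) -> float:
    """Molecular-interaction rate ±k·A for the additive expression update.

    ``sign=-1`` when the interacting molecule A (e.g. an activated immune
    signal) consumes/downregulates the gene product; ``+1`` when it
    promotes production.
    """
    if k < 0 or A < 0:
        raise ValueError("k and A must be nonnegative")
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    return sign * k * A


def initial_cell_count(V0: float, avg_cell_size: float) -> int:
    """Initial agent count N0 = floor(V0 / average cell size).

    A positive tumor volume maps to at least one agent; agents are whole
    cells, so the quotient is floored.
    """
    if avg_cell_size <= 0:
        raise ValueError("avg_cell_size must be positive")
    if V0 < 0:
        raise ValueError("V0 must be nonnegative")
    if V0 == 0:
        return 0
    return max(1, int(math.floor(V0 / avg_cell_size)))
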