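"""Closed-form solvers for the expression-kinetics ODEs.

Three small linear systems describe how measured expression signal arises
and decays:

* **Probe binding** (microarray hybridization): unbound probe ``B`` binds
  target at rate ``k_h·[T]`` and bound complex dissociates at rate ``k_d``,

  .. math:: dB/dt = -k_h [T] B + k_d (B_{max} - B).

* **Transcript dynamics** (RNA-seq): reactant ``R`` and product ``M`` with

  .. math:: dR/dt = (k_t - k_{dr}) R, \\qquad dM/dt = k_{dr} R - k_{dm} M.

* **Spatial expression field**: per-site concentration with local creation
  ``k_trans(t)`` and first-order degradation ``k_deg``,

  .. math:: dM_{ij}/dt = k_{trans}(t) - k_{deg} M_{ij}.

All three are linear, so the first two are solved exactly (with stable
handling of the degenerate-eigenvalue case via :func:`numpy.expm1`); the
field, whose creation rate may be an arbitrary function of time, is stepped
with explicit Euler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

__all__ = [
    "BindingParams",
    "TranscriptParams",
    "FieldParams",
    "solve_binding",
    "solve_transcript",
    "field_step",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class BindingParams:
    """Hybridization kinetics: probe B binding a target T in excess.

    Parameters
    ----------
    B0 : initial unbound probe concentration.
    k_h : binding rate constant (per concentration per time).
    T_total : total target concentration ``[T]`` (held constant).
    k_d : dissociation rate constant (per time).
    B_max : total probe concentration (bound + unbound).
    """

    B0: float
    k_h: float
    T_total: float
    k_d: float
    B_max: float

    def __post_init__(self) -> None:
        for name in ("B0", "k_h", "T_total", "k_d", "B_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.B0 > self.B_max:
            raise ValueError("B0 cannot exceed B_max")

    @property
    def equilibrium(self) -> float:
        """Fixed point B* = k_d·B_max / (k_h·[T] + k_d); B_max if all rates 0."""
        lam = self.k_h * self.T_total + self.k_d
        if lam == 0.0:
            return self.B0
        return self.k_d * self.B_max / lam


@dataclass(frozen=True)
class TranscriptParams:
    """Transcript synthesis/decay: reactant R feeding product M."""

    R0: float
    M0: float
    k_t: float
    k_dr: float
    k_dm: float
    sign_flip: bool = False
    """If True, use dR/dt = (k_dr − k_t)·R, the sign convention of the
    prose description rather than the displayed equation. Off by default."""

    def __post_init__(self) -> None:
        for name in ("R0", "M0", "k_t", "k_dr", "k_dm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class FieldParams:
    """Per-site expression field: creation rate k_trans(t), decay k_deg."""

    k_trans: Union[float, Callable[[float], ArrayLike]]
    k_deg: float

    def __post_init__(self) -> None:
        if self.k_deg < 0:
            raise ValueError("k_deg must be nonnegative")

    def creation_rate(self, t: float) -> ArrayLike:
        if callable(self.k_trans):
            return self.k_trans(t)
        return self.k_trans


def solve_binding(p: BindingParams, t: ArrayLike) -> ArrayLike:
    """Exact B(t) for the linear binding ODE.

    B(t) = B* + (B0 − B*)·exp(−λt) with λ = k_h·[T] + k_d and
    B* = k_d·B_max/λ. Converges to B* as t → ∞.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    lam = p.k_h * p.T_total + p.k_d
    if lam == 0.0:
        out = np.full_like(t, p.B0)
    else:
        b_star = p.k_d * p.B_max / lam
        out = b_star + (p.B0 - b_star) * np.exp(-lam * t)
    return out if out.ndim else float(out)


def _phi(a: ArrayLike, t: np.ndarray) -> np.ndarray:
    """Stable (e^{a t} − 1)/a, with the a → 0 limit t."""
    a = float(a)
    if a == 0.0:
        return t.astype(float)
    return np.expm1(a * t) / a


def solve_transcript(p: TranscriptParams, t: ArrayLike) -> tuple:
    """Exact (R(t), M(t)) for the transcript system.

    R grows/decays exponentially with rate a = k_t − k_dr; M integrates
    the k_dr·R source against its own decay k_dm:

        M(t) = M0·e^{−k_dm t} + k_dr·R0·e^{−k_dm t}·(e^{(a+k_dm)t} − 1)/(a+k_dm)

    The degenerate eigenvalue a = −k_dm is the (e^x − 1)/x → x limit and is
    handled without branching error by expm1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    a = (p.k_dr - p.k_t) if p.sign_flip else (p.k_t - p.k_dr)
    R = p.R0 * np.exp(a * t)
    decay = np.exp(-p.k_dm * t)
    M = p.M0 * decay + p.k_dr * p.R0 * decay * _phi(a + p.k_dm, t)
    if t.ndim:
        return R, M
    return float(R), float(M)


def field_step(M: ArrayLike, p: FieldParams, t: float, dt: float) -> ArrayLike:
    """One explicit-Euler update of the expression field.

    M ← M + dt·(k_trans(t) − k_deg·M). Sites are independent — the field
    equation carries no diffusion term; spatial nutrient transport is the
    agent model's job.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    M = np.asarray(M, dtype=float)
    out = M + dt * (np.asarray(p.creation_rate(t), dtype=float) - p.k_deg * M)
    return out if out.ndim else float(out)
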