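"""Shared fixtures and the fixed-step RK4 oracle used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from prognosim import synthetic


def rk4(f, y0, t_end, n_steps=2000):
    """Classical fixed-step Runge–Kutta 4 integration of dy/dt = f(t, y).

    Independent of every solver in the package: used as the numerical
    oracle for the closed-form kinetics and growth solutions.
    """
    y = np.asarray(y0, dtype=float)
    h = t_end / n_steps
    t = 0.0
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort with expression columns, no missingness."""
    return synthetic.generate_cohort(
        synthetic.CohortSpec(n_patients=300, n_genes=4, seed=42)
    )


@pytest.fixture(scope="session")
def large_cohort():
    """5000-patient cohort for Monte-Carlo shape/hazard checks."""
    return synthetic.generate_cohort(synthetic.CohortSpec(n_patients=5000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
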