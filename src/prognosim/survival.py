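"""SVD-compressed logistic survival model with time-derivative extrapolation.

For each horizon t the standardized patient-by-feature matrix X is
compressed onto the leading right-singular vectors (retained until a
target fraction — 90% by default — of cumulative variance is explained)
and an L2-penalized logistic classifier is fitted on the projected
coordinates SV = X·ω:

    f(SV, t) = 1 / (1 + exp(−(β₀(t) + β₁SV₁ + … + β_m SV_m)))

Because the projection is linear, the same model is exactly expressible
in raw feature space,

    f(X, t) = 1 / (1 + exp(−(β₀(t) + Σᵢ Σⱼ ω_ij β_j(t) X_i))),

an identity this module maintains to machine precision (``predict_prob``
offers both routes). Treating the singular-vector weights ω as
time-independent, the horizon derivative of f reduces to the scalar

    θ(t) = ∂β₀/∂t + Σᵢ Σⱼ ω_ij (∂β_j/∂t) X_i,

with ∂β/∂t estimated by finite differences across the fitted horizons.
Two first-order extrapolation rules for f(X, t+Δt) are provided:
``taylor`` applies the logistic chain rule f' = f(1−f)θ, while ``paper``
uses the variant slope (f−1)θ, i.e. f(θΔt+1) − θΔt; the chain rule is the
default and the variant is retained for fidelity to the derivation it
comes from.

A gamma-CDF regression of predicted survival probability on a single
count-valued feature (mutation burden, positive lymph nodes) summarizes
probability–feature relationships as smooth monotone curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SvdBasis",
    "SubsetModel",
    "GammaFit",
    "ThetaEvaluation",
    "fit_svd",
    "project",
    "fit_logistic",
    "predict_prob",
    "predict_prob_sv",
    "beta_derivatives",
    "theta",
    "extrapolate",
    "logistic_derivative_check",
    "fit_gamma_cdf",
    "models_to_json",
    "models_from_json",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    # saturated logits stay strictly inside (0, 1) in float arithmetic
    return np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


# --------------------------------------------------------------------------
# SVD feature compression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SvdBasis:
    """Feature-weight matrix ω (n_features × m) of the retained singular vectors."""

    omega: np.ndarray
    singular_values: np.ndarray
    var_target: float
    m: int
    feature_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.omega.shape[1] != self.m:
            raise ValueError("omega must have m columns")


def fit_svd(X: np.ndarray, var_target: float = 0.90) -> SvdBasis:
    """Retain the smallest number of singular vectors reaching the variance target.

    X is assumed standardized (zero mean, unit variance per feature) —
    mixed clinical units make raw-scale SVD meaningless. Explained
    variance is the squared-singular-value fraction; ω holds orthonormal
    right-singular vectors as columns.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X must be nonempty")
    if not (0.0 < var_target <= 1.0):
        raise ValueError("var_target must lie in (0, 1]")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    power = s**2
    total = power.sum()
    if total == 0:
        raise ValueError("X has no variance")
    cum = np.cumsum(power) / total
    m = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    m = min(m, int((s > s[0] * 1e-12).sum()))  # never exceed numerical rank
    return SvdBasis(Vt[:m].T.copy(), s.copy(), var_target, m)


def project(X: np.ndarray, basis: SvdBasis) -> np.ndarray:
    """Singular-vector coordinates SV = X·ω."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != basis.omega.shape[0]:
        raise ValueError(
            f"feature count mismatch: X has {X.shape[-1]}, basis expects {basis.omega.shape[0]}"
        )
    return X @ basis.omega


# --------------------------------------------------------------------------
# per-horizon logistic model
# --------------------------------------------------------------------------


@dataclass
class SubsetModel:
    """Fitted logistic model for one horizon t, in SV coordinates."""

    t: int
    beta0: float
    beta: np.ndarray
    basis: SvdBasis
    cv_auc: float
    folds: int

    @property
    def feature_coefficients(self) -> np.ndarray:
        """Composed raw-feature coefficients Σⱼ ω_ij β_j."""
        return self.basis.omega @ self.beta


def fit_logistic(
    SV: np.ndarray,
    y: np.ndarray,
    t: int = 0,
    basis: Optional[SvdBasis] = None,
    folds: int = 20,
    C: float = 1.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> SubsetModel:
    """L2-penalized logistic fit with stratified-CV AUC.

    liblinear, 1000 iterations, L2 penalty; the mean AUC-ROC over
    stratified folds (folds capped at the minority-class count) is the
    headline accuracy metric because the outcome classes are imbalanced.
    The final coefficients come from a fit on all rows.
    """
    SV = np.asarray(SV, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    n_splits = int(min(folds, counts.min()))
    if n_splits < 2:
        raise ValueError("too few minority-class samples for cross-validation")

    def make_clf():
        # default penalty is L2; passing it explicitly is deprecated upstream
        return LogisticRegression(C=C, solver="liblinear", max_iter=max_iter, random_state=seed)

    aucs = []
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train, test in skf.split(SV, y):
        if np.unique(y[train]).size < 2:
            continue
        clf = make_clf().fit(SV[train], y[train])
        aucs.append(roc_auc_score(y[test], clf.decision_function(SV[test])))
    clf = make_clf().fit(SV, y)
    basis = basis if basis is not None else SvdBasis(
        np.eye(SV.shape[1]), np.ones(SV.shape[1]), 1.0, SV.shape[1]
    )
    return SubsetModel(
        t=int(t),
        beta0=float(clf.intercept_[0]),
        beta=clf.coef_[0].copy(),
        basis=basis,
        cv_auc=float(np.mean(aucs)),
        folds=n_splits,
    )


def predict_prob_sv(model: SubsetModel, SV: np.ndarray) -> np.ndarray:
    """P(class 1) evaluated in singular-vector space."""
    SV = np.asarray(SV, dtype=float)
    if SV.shape[-1] != model.beta.size:
        raise ValueError("SV width does not match coefficient count")
    return _sigmoid(model.beta0 + SV @ model.beta)


def predict_prob(model: SubsetModel, X: np.ndarray, space: str = "feature") -> np.ndarray:
    """P(class 1) from raw features.

    ``space='feature'`` uses the composed coefficients ω·β directly;
    ``space='sv'`` projects first. The two are algebraically identical
    and agree to machine precision.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.basis.omega.shape[0]:
        raise ValueError("feature count mismatch")
    if space == "sv":
        return predict_prob_sv(model, project(X, model.basis))
    if space == "feature":
        return _sigmoid(model.beta0 + X @ model.feature_coefficients)
    raise ValueError("space must be 'feature' or 'sv'")


# --------------------------------------------------------------------------
# horizon derivative and extrapolation
# --------------------------------------------------------------------------


@dataclass
class ThetaEvaluation:
    """θ(t) per sample, and the corresponding slope ∂f/∂t under the chosen mode."""

    t: int
    theta: np.ndarray
    dfdt: np.ndarray
    mode: str


def _check_shared_basis(models: Sequence[SubsetModel]) -> None:
    if len(models) < 2:
        raise ValueError("need at least two horizon models")
    first = models[0].basis
    for m in models[1:]:
        if m.basis.omega.shape != first.omega.shape or not np.array_equal(
            m.basis.omega, first.omega
        ):
            raise ValueError("all models must share one SVD basis")


def beta_derivatives(models: Sequence[SubsetModel]) -> dict:
    """Finite-difference ∂β₀/∂t and ∂β/∂t at each fitted horizon.

    Centered differences at interior horizons, one-sided at the ends.
    Returns {t: (dbeta0_dt, dbeta_dt)}.
    """
    _check_shared_basis(models)
    models = sorted(models, key=lambda m: m.t)
    ts = np.array([m.t for m in models], dtype=float)
    if np.unique(ts).size != ts.size:
        raise ValueError("horizons must be distinct")
    b0 = np.array([m.beta0 for m in models])
    B = np.vstack([m.beta for m in models])
    d0 = np.gradient(b0, ts)
    dB = np.gradient(B, ts, axis=0)
    return {int(ts[i]): (float(d0[i]), dB[i]) for i in range(len(models))}


def theta(
    models: Sequence[SubsetModel],
    X: np.ndarray,
    t: Optional[int] = None,
    mode: str = "taylor",
) -> ThetaEvaluation:
    """Evaluate θ(t) = ∂β₀/∂t + Σᵢ Σⱼ ω_ij (∂β_j/∂t) X_i per sample.

    ω is treated as time-independent, so only the β trajectory moves.
    ``dfdt`` is f(1−f)·θ under ``mode='taylor'`` (the logistic chain rule)
    or (f−1)·θ under ``mode='paper'``.
    """
    if mode not in ("taylor", "paper"):
        raise ValueError("mode must be 'taylor' or 'paper'")
    derivs = beta_derivatives(models)
    models = sorted(models, key=lambda m: m.t)
    if t is None:
        t = models[0].t
    if t not in derivs:
        raise ValueError(f"no model fitted at horizon t={t}")
    model = next(m for m in models if m.t == t)
    d0, dB = derivs[t]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    th = d0 + X @ (model.basis.omega @ dB)
    f = predict_prob(model, X)
    dfdt = f * (1.0 - f) * th if mode == "taylor" else (f - 1.0) * th
    return ThetaEvaluation(int(t), th, dfdt, mode)


def extrapolate(f, theta_val, dt: float, mode: str = "taylor"):
    """First-order probability extrapolation f(t) → f(t+Δt), clamped to [0,1].

    taylor: f + f(1−f)·θ·Δt.   paper: f·(θΔt + 1) − θΔt = f + (f−1)·θ·Δt.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("f must lie strictly in (0, 1)")
    theta_val = np.asarray(theta_val, dtype=float)
    if mode == "taylor":
        out = f + f * (1.0 - f) * theta_val * dt
    elif mode == "paper":
        out = f + (f - 1.0) * theta_val * dt
    else:
        raise ValueError("mode must be 'taylor' or 'paper'")
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def logistic_derivative_check(x: float, h: float = 1e-6) -> Tuple[float, float]:
    """(central-difference f′(x), closed form f(x)(1−f(x))).

    The closed form equals ¼·sech²(x/2); both identities are exercised in
    the test suite.
    """
    x = float(x)
    f = lambda z: 1.0 / (1.0 + np.exp(-z))
    numeric = (f(x + h) - f(x - h)) / (2.0 * h)
    closed = f(x) * (1.0 - f(x))
    return numeric, closed


# --------------------------------------------------------------------------
# gamma-CDF probability curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaFit:
    """p(x) ≈ a·(1 − GammaCDF(x; k, θ)) + c — nonincreasing in x when a > 0."""

    shape: float
    scale: float
    amplitude: float
    offset: float
    sse: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.amplitude * stats.gamma.sf(x, a=self.shape, scale=self.scale) + self.offset


def fit_gamma_cdf(x: Sequence[float], p: Sequence[float]) -> GammaFit:
    """Least-squares gamma survival-curve fit of probability against a feature.

    Shape and scale are optimized in log space (keeping them positive);
    five deterministic multi-starts over a shape/scale grid guard against
    local minima of the non-convex residual surface.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.size != p.size:
        raise ValueError("x and p must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a gamma curve")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")

    span = p.max() - p.min()
    scale0 = max(np.mean(x), 1e-3)

    def residual(params):
        logk, logth, a, c = params
        return a * stats.gamma.sf(x, a=np.exp(logk), scale=np.exp(logth)) + c - p

    best = None
    for k0, s0 in ((1.0, scale0), (2.0, scale0 / 2), (0.5, scale0), (4.0, scale0 / 4), (2.0, scale0)):
        start = np.array([np.log(k0), np.log(s0), span if span > 0 else 0.1, p.min()])
        res = least_squares(residual, start, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
        if best is None or res.cost < best.cost:
            best = res
    logk, logth, a, c = best.x
    return GammaFit(
        shape=float(np.exp(logk)),
        scale=float(np.exp(logth)),
        amplitude=float(a),
        offset=float(c),
        sse=float(2.0 * best.cost),
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def models_to_json(models: Sequence[SubsetModel]) -> str:
    """Serialize horizon models + shared basis to a documented JSON schema."""
    _check_shared_basis(models)
    basis = models[0].basis
    doc = {
        "schema": "prognosim-subset-models-v1",
        "var_target": basis.var_target,
        "m": basis.m,
        "feature_names": list(basis.feature_names) if basis.feature_names else None,
        "omega": basis.omega.tolist(),
        "singular_values": basis.singular_values.tolist(),
        "models": [
            {
                "t": m.t,
                "beta0": m.beta0,
                "beta": m.beta.tolist(),
                "cv_auc": m.cv_auc,
                "folds": m.folds,
            }
            for m in sorted(models, key=lambda m: m.t)
        ],
    }
    return json.dumps(doc, indent=2)


def models_from_json(text: str) -> List[SubsetModel]:
    doc = json.loads(text)
    basis = SvdBasis(
        omega=np.asarray(doc["omega"], dtype=float),
        singular_values=np.asarray(doc["singular_values"], dtype=float),
        var_target=float(doc["var_target"]),
        m=int(doc["m"]),
        feature_names=tuple(doc["feature_names"]) if doc.get("feature_names") else None,
    )
    return [
        SubsetModel(
            t=int(m["t"]),
            beta0=float(m["beta0"]),
            beta=np.asarray(m["beta"], dtype=float),
            basis=basis,
            cv_auc=float(m["cv_auc"]),
            folds=int(m["folds"]),
        )
        for m in doc["models"]
    ]
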