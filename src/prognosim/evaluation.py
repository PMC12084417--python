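"""Concordance, ROC/AUC, confusion matrices and calibration curves.

The concordance index is the fraction of comparable patient pairs whose
predicted ranking agrees with the observed survival ordering: 1 is
perfect agreement, 0.5 is random. With censoring, a pair is comparable
only when the patient with the shorter observed time actually had the
event (Harrell's rule) — a censored short time tells us nothing about
who outlived whom. Tied predictions count half; pairs tied on time are
skipped.

TPR/FPR follow the set definitions TPR = |S(t)∩G|/|G| and
FPR = |S(t)−G|/|D−G| (S(t): cases called positive at threshold t, G:
ground-truth positives, D: everything); sweeping the threshold over every
observed score yields the ROC curve, whose trapezoidal area equals the
probability that a random positive outscores a random negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RocCurve",
    "ConfusionMatrix",
    "CalibrationBins",
    "c_index",
    "tpr_fpr",
    "roc_auc",
    "confusion",
    "calibration_curve",
    "bootstrap_ci",
]


def c_index(
    T_pred: Sequence[float],
    T_actual: Sequence[float],
    events: Optional[Sequence[int]] = None,
) -> float:
    """Concordance between predicted survival scores and observed times.

    Higher predicted score must mean longer observed survival for a pair
    to count as concordant. ``events`` marks observed deaths (1) vs
    censoring (0); omitted means fully observed.
    """
    pred = np.asarray(T_pred, dtype=float)
    time = np.asarray(T_actual, dtype=float)
    if pred.shape != time.shape or pred.ndim != 1:
        raise ValueError("T_pred and T_actual must be equal-length 1-D arrays")
    ev = np.ones_like(time, dtype=bool) if events is None else np.asarray(events).astype(bool)
    if ev.shape != time.shape:
        raise ValueError("events must match the time array")

    concordant = 0.0
    comparable = 0
    for i in np.flatnonzero(ev):
        # pairs (i, j) with time_i < time_j are comparable: i's event precedes j
        longer = time > time[i]
        n_j = int(longer.sum())
        if n_j == 0:
            continue
        comparable += n_j
        diff = pred[longer] - pred[i]
        concordant += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return float(concordant / comparable)


def tpr_fpr(
    scores: Sequence[float], y: Sequence[int], threshold: float
) -> Tuple[float, float]:
    """True/false positive rates at one score threshold (call positive when ≥).

    Returned as fractions; multiply by 100 for the percent rendering.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = y == 1
    if not pos.any():
        raise ValueError("no positive cases")
    if pos.all():
        raise ValueError("no negative cases")
    called = scores >= threshold
    tpr = float((called & pos).sum() / pos.sum())
    fpr = float((called & ~pos).sum() / (~pos).sum())
    return tpr, fpr


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], y: Sequence[int]) -> RocCurve:
    """ROC curve over all score thresholds, AUC by the trapezoid rule."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    # descending thresholds: +inf start gives the (0, 0) corner
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    tp = np.empty(thresholds.size)
    fp = np.empty(thresholds.size)
    cum_tp = np.cumsum(y_sorted == 1)
    cum_fp = np.cumsum(y_sorted == 0)
    for k, thr in enumerate(thresholds):
        idx = int(np.searchsorted(-s_sorted, -thr, side="right"))
        tp[k] = cum_tp[idx - 1] if idx else 0
        fp[k] = cum_fp[idx - 1] if idx else 0
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, tpr, fpr, auc)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion(scores: Sequence[float], y: Sequence[int], threshold: float) -> ConfusionMatrix:
    """2×2 counts at one threshold (positive call when score ≥ threshold)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    called = scores >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int((called & pos).sum()),
        fp=int((called & ~pos).sum()),
        tn=int((~called & ~pos).sum()),
        fn=int((~called & pos).sum()),
    )


@dataclass(frozen=True)
class CalibrationBins:
    edges: np.ndarray
    mean_pred: np.ndarray
    frac_obs: np.ndarray
    counts: np.ndarray


def calibration_curve(
    p_pred: Sequence[float], y: Sequence[int], n_bins: int = 10
) -> CalibrationBins:
    """Equal-width reliability bins on [0, 1]; empty bins are omitted.

    Per occupied bin: the mean predicted probability and the observed
    event fraction — coincident values mean a well-calibrated model.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    p = np.asarray(p_pred, dtype=float)
    y = np.asarray(y).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    mean_pred, frac_obs, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        mean_pred.append(p[sel].mean())
        frac_obs.append(y[sel].mean())
        counts.append(int(sel.sum()))
    return CalibrationBins(edges, np.array(mean_pred), np.array(frac_obs), np.array(counts))


def bootstrap_ci(
    metric: Callable[..., float],
    *arrays: Sequence,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for any row-aligned metric (95% by default)."""
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(metric(*(a[idx] for a in arrays)))
        except ValueError:
            continue  # degenerate resample (e.g. single class)
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
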