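"""Minimal figure writers for ROC, calibration and growth trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import CalibrationBins, RocCurve  # noqa: E402

__all__ = ["save_roc_plot", "save_calibration_plot", "save_trajectory_plot"]


def save_roc_plot(curve: RocCurve, path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, label=f"{label} AUC={curve.auc:.3f}".strip())
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_calibration_plot(bins: CalibrationBins, path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(bins.mean_pred, bins.frac_obs, "o-", label=label or None)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event fraction")
    if label:
        ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_trajectory_plot(result, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    steps = range(len(result.N_series))
    ax.plot(steps, result.N_series, label="N (cells)")
    ax.plot(steps, result.S_series, label="S (total size)")
    if result.T_relapse is not None:
        ax.axvline(result.T_relapse, ls=":", c="red", label=f"relapse @ {result.T_relapse}")
    ax.set_xlabel("step")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
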