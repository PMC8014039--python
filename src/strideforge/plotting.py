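"""Diagnostic plots: Bland-Altman agreement, error CDF, RMSE convergence."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from strideforge.evaluation import bland_altman

__all__ = ["bland_altman_plot", "error_cdf_plot", "personalization_curve_plot"]


def bland_altman_plot(
    v_est: np.ndarray,
    v_ref: np.ndarray,
    path: str | Path | None = None,
    subjects: np.ndarray | None = None,
):
    """Difference vs mean with limits of agreement and the linear trend.

    When ``subjects`` is given, per-subject mean points are overlaid on the
    per-step cloud.
    """
    v_est = np.asarray(v_est, dtype=float)
    v_ref = np.asarray(v_ref, dtype=float)
    ba = bland_altman(v_est, v_ref)
    mean = 0.5 * (v_est + v_ref)
    diff = v_est - v_ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mean, diff, ".", color="0.6", ms=2, alpha=0.4, label="steps")
    if subjects is not None:
        df = pd.DataFrame({"m": mean, "d": diff, "s": subjects}).groupby("s").mean()
        ax.plot(df.m, df.d, "o", mfc="none", color="tab:blue", label="subjects")
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    xs = np.linspace(mean.min(), mean.max(), 2)
    ax.plot(xs, ba.trend_slope * xs + ba.trend_intercept, "b--", lw=1,
            label=f"y = {ba.trend_slope:.4f}x{ba.trend_intercept:+.3f}")
    ax.set_xlabel("mean of estimate and reference (m/s)")
    ax.set_ylabel("estimate − reference (m/s)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def error_cdf_plot(cdf: pd.DataFrame, path: str | Path | None = None):
    """Per-group (gray) and pooled (blue) CDF of absolute step errors."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in cdf.columns:
        if col != "pooled":
            ax.plot(cdf.index, cdf[col], color="0.7", lw=0.8)
    ax.plot(cdf.index, cdf["pooled"], color="tab:blue", lw=2, label="pooled")
    ax.set_xlabel("absolute error (m/s)")
    ax.set_ylabel("fraction of steps")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def personalization_curve_plot(
    curves: list[pd.DataFrame], path: str | Path | None = None
):
    """Inter-subject mean ± STD of test RMSE vs strides consumed."""
    merged = pd.concat(
        [c.set_index("strides").rmse.rename(i) for i, c in enumerate(curves)],
        axis=1,
    ).interpolate()
    mean, std = merged.mean(axis=1), merged.std(axis=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mean.index, mean, color="tab:blue")
    ax.fill_between(mean.index, mean - std, mean + std, color="tab:blue", alpha=0.25)
    ax.set_xlabel("strides used for personalization")
    ax.set_ylabel("test RMSE (m/s)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
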