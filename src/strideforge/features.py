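"""Per-stride feature engineering for the linear speed model.

Eleven statistics (mean, std, median, IQR, max, RMS, kurtosis, skewness and
the three coefficients of an order-3 autoregressive fit) are computed over
each stride window [IC_i, IC_i+2) for every channel of the acceleration,
angular velocity and drift-corrected foot velocity (x, y, z, norm) plus the
slope series, giving 143 signal statistics per stride.  Temporal parameters
(CT, FLT, SWT, STP, STR) and the pitch angle at IC complete the 149 base
features; each base feature is augmented with three linearizing transforms
f1(p) = p^2, f2(p) = p^3 and f3(p) = 1/p (columns ``f1(name)`` etc.), and
four anthropometric candidates (height, weight, gender, age) are appended
untransformed -- 600 candidate features per step.

Conventions (configurable where noted): sample std with ddof=1; skewness
and kurtosis are the biased moment ratios (kurtosis non-excess, Pearson);
IQR uses linear-interpolation quantiles; AR(3) by Yule-Walker on the
mean-removed window with MLE autocovariance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strideforge.events import GaitCycleTable
from strideforge.gnss import ReferenceSpeed
from strideforge.kinematics import FootStateSeries
from strideforge.preprocess import IMURecording, SlopeSeries
from strideforge.simulate import Subject

__all__ = [
    "STAT_NAMES",
    "StrideFeatureTable",
    "channel_statistics",
    "linearize",
    "robust_normalize",
    "assemble_step_rows",
    "average_inputs",
    "build_stride_features",
    "P_MANUAL",
    "P_AUTO_BEST",
    "P_MANUAL_BEST",
]

STAT_NAMES = ("mean", "std", "median", "iqr", "max", "rms", "kurt", "skew",
              "arm1", "arm2", "arm3")
TEMPORAL_NAMES = ("CT", "FLT", "SWT", "STP", "STR")
ANTHRO_NAMES = ("height", "weight", "gender", "age")

#: comprehensive feature set chosen for biomechanical relevance
P_MANUAL = ["height", "CT", "FLT", "STR", "mean_vfoot_norm", "max_omega_z",
            "rms_omega_norm", "max_a_norm", "mean_s"]
#: the sparse model the LASSO consistently keeps from the stepwise-selected set
P_AUTO_BEST = ["mean_a_norm", "f1(mean_s)", "f3(STR)", "f2(median_omega_z)",
               "max_vfoot_norm", "f1(mean_vfoot_y)", "f3(median_omega_norm)"]
#: the sparse model the LASSO keeps from the comprehensive set
P_MANUAL_BEST = ["rms_omega_norm", "mean_vfoot_norm", "mean_s", "CT"]


@dataclass
class StrideFeatureTable:
    """One row per valid step: features, label, subject and foot ids.

    ``feature_cols`` lists every candidate feature column (base +
    transformed + anthropometric); ``label`` is the step's reference speed.
    """

    df: pd.DataFrame
    feature_cols: list[str]
    norm_stats: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.df)

    def features(self) -> pd.DataFrame:
        return self.df[self.feature_cols]

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def subjects(self) -> np.ndarray:
        return self.df["subject"].to_numpy()


def _batched_yule_walker(x: np.ndarray, order: int = 3) -> np.ndarray:
    """AR coefficients per column by Yule-Walker (MLE autocovariance).

    ``x`` has shape (n, c); returns (order, c).  Singular systems give NaN
    for the affected column.
    """
    n, c = x.shape
    xc = x - x.mean(axis=0)
    acov = np.empty((order + 1, c))
    for k in range(order + 1):
        acov[k] = np.einsum("ij,ij->j", xc[k:], xc[: n - k]) / n
    out = np.full((order, c), np.nan)
    for j in range(c):
        R = np.empty((order, order))
        for a in range(order):
            for b in range(order):
                R[a, b] = acov[abs(a - b), j]
        try:
            out[:, j] = np.linalg.solve(R, acov[1:, j])
        except np.linalg.LinAlgError:
            pass
    return out


def channel_statistics(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The 11 per-channel statistics of a stride window.

    ``window`` has shape (n, c) with n >= 8.  Returns ``(stats, flags)``
    where ``stats`` is (11, c) ordered as :data:`STAT_NAMES` and ``flags``
    marks channels whose shape statistics were undefined (constant window)
    and were set to 0.
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    if w.ndim == 1:
        w = w[:, None]
    n, c = w.shape
    if n < 8:
        raise ValueError("stride window must hold at least 8 samples")
    mean = w.mean(axis=0)
    xc = w - mean
    m2 = (xc**2).mean(axis=0)
    m3 = (xc**3).mean(axis=0)
    m4 = (xc**4).mean(axis=0)
    std = w.std(axis=0, ddof=1)
    med = np.median(w, axis=0)
    q75, q25 = np.percentile(w, [75, 25], axis=0)
    mx = w.max(axis=0)
    rms = np.sqrt((w**2).mean(axis=0))
    degenerate = m2 <= 0
    safe_m2 = np.where(degenerate, 1.0, m2)
    skew = np.where(degenerate, 0.0, m3 / safe_m2**1.5)
    kurt = np.where(degenerate, 0.0, m4 / safe_m2**2)
    ar = _batched_yule_walker(w, order=3)
    ar_bad = ~np.isfinite(ar).all(axis=0)
    ar = np.where(np.isfinite(ar), ar, 0.0)
    stats = np.vstack([mean, std, med, q75 - q25, mx, rms, kurt, skew, ar])
    return stats, degenerate | ar_bad


def linearize(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Append f1(p)=p^2, f2(p)=p^3, f3(p)=1/p columns for every base feature.

    f3 of a zero-valued feature yields inf; such entries are masked to NaN
    (the row is kept, the transformed column is unusable for that row).
    Returns the widened frame and the full candidate column list.
    """
    base = df[cols].to_numpy(dtype=float)
    out = {}
    for i, name in enumerate(cols):
        p = base[:, i]
        out[f"f1({name})"] = p**2
        out[f"f2({name})"] = p**3
        with np.errstate(divide="ignore"):
            inv = np.where(p != 0, 1.0 / np.where(p != 0, p, 1.0), np.nan)
        out[f"f3({name})"] = inv
    widened = pd.concat([df, pd.DataFrame(out, index=df.index)], axis=1)
    return widened, cols + list(out.keys())


def robust_normalize(
    df: pd.DataFrame,
    cols: list[str],
    stats: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Robust z-score: subtract the mean, divide by the (unscaled) MAD.

    After normalization each column has mean 0 and median absolute
    deviation 1.  When ``stats`` is given (a frame with ``mean``/``mad``
    per column, from a training set) those statistics are applied instead
    of refitting -- held-out subjects never contribute to them.  Columns
    with MAD 0 are flagged constant (``usable == False``) and left
    centered but unscaled.
    """
    out = df.copy()
    if stats is None:
        mean = df[cols].mean()
        med = df[cols].median()
        mad = (df[cols] - med).abs().median()
        stats = pd.DataFrame({"mean": mean, "mad": mad})
        stats["usable"] = stats["mad"] > 0
    scale = stats["mad"].where(stats["usable"], 1.0)
    out[cols] = (df[cols] - stats["mean"]) / scale
    return out, stats


def _slope_window(slope: SlopeSeries, t0: float, t1: float) -> np.ndarray:
    m = (slope.time >= t0) & (slope.time < t1)
    if m.any():
        return slope.slope[m]
    i = int(np.argmin(np.abs(slope.time - 0.5 * (t0 + t1))))
    return slope.slope[i : i + 1]


def build_stride_features(
    recordings: dict[str, IMURecording],
    table: GaitCycleTable,
    states: dict[str, FootStateSeries],
    slope: SlopeSeries,
    subject: Subject,
) -> pd.DataFrame:
    """Raw per-step feature rows (before labels and normalization).

    Each step carries the features of the stride initiated by its foot:
    the 11 statistics over [IC_i, IC_i+2) for the 13 signal channels, the
    temporal parameters, the pitch at IC and the anthropometrics.
    """
    fs = table.fs
    rows = []
    for _, step in table.valid().iterrows():
        foot = step.foot
        rec, state = recordings[foot], states[foot]
        i0 = int(step.ic_idx)
        i1 = i0 + int(round(step["str"] * fs))
        if i1 > rec.n_samples or not state.integrated[i0:i1].all():
            continue
        sig = np.column_stack(
            [
                rec.acc[i0:i1],
                np.linalg.norm(rec.acc[i0:i1], axis=1),
                rec.gyr[i0:i1],
                np.linalg.norm(rec.gyr[i0:i1], axis=1),
                state.v_ff[i0:i1],
                np.linalg.norm(state.v_ff[i0:i1], axis=1),
            ]
        )
        stats, _ = channel_statistics(sig)
        names = []
        for signal, chans in (("a", "xyzn"), ("omega", "xyzn"), ("vfoot", "xyzn")):
            for ch in chans:
                names.append((signal, "norm" if ch == "n" else ch))
        row = {}
        for j, (signal, ch) in enumerate(names):
            for k, stat in enumerate(STAT_NAMES):
                row[f"{stat}_{signal}_{ch}"] = stats[k, j]
        s_win = _slope_window(slope, step.ic, step.ic + step["str"])
        if s_win.size >= 8:
            s_stats, _ = channel_statistics(s_win[:, None])
            s_col = s_stats[:, 0]
        else:
            pad = np.resize(s_win, 8)[:, None]
            s_stats, _ = channel_statistics(pad)
            s_col = s_stats[:, 0]
        for k, stat in enumerate(STAT_NAMES):
            row[f"{stat}_s"] = s_col[k]
        row.update(
            CT=step.ct, FLT=step.flt, SWT=step.swt, STP=step.stp, STR=step["str"],
            theta=float(state.theta[i0]),
        )
        row.update(
            foot=foot, ic=step.ic, stp=step.stp, subject=subject.subject_id,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_step_rows(
    raw_rows: pd.DataFrame,
    ref: ReferenceSpeed,
    subject: Subject,
) -> StrideFeatureTable:
    """Attach labels and anthropometrics; apply the linearizing transforms.

    The label of step i is the mean reference speed over [IC_i, IC_i+1).
    Steps without reference coverage are dropped (count in ``meta``).
    """
    df = raw_rows.sort_values("ic").reset_index(drop=True)
    labels = np.array(
        [ref.mean_over(r.ic, r.ic + r.stp) for r in df.itertuples()]
    )
    dropped = int(np.isnan(labels).sum())
    df["label"] = labels
    df = df[np.isfinite(labels)].reset_index(drop=True)

    base_cols = [c for c in df.columns
                 if c not in ("foot", "ic", "stp", "subject", "label")]
    df, feature_cols = linearize(df, base_cols)
    for name, value in zip(
        ANTHRO_NAMES, (subject.height, subject.weight, subject.gender, subject.age)
    ):
        df[name] = float(value)
    feature_cols = feature_cols + list(ANTHRO_NAMES)
    return StrideFeatureTable(
        df=df, feature_cols=feature_cols,
        meta={"dropped_no_reference": dropped, "n_base_features": len(base_cols)},
    )


def average_inputs(table: StrideFeatureTable, k: int) -> StrideFeatureTable:
    """Average features and labels over non-overlapping blocks of k steps.

    ``k`` must be even (both feet contribute equally); k = 1 is the
    identity.  Blocks are formed within each subject in time order;
    trailing partial blocks are dropped.
    """
    if k == 1:
        return table
    if k % 2 != 0:
        raise ValueError("k must be even (or 1)")
    num_cols = table.feature_cols + ["label", "ic"]
    frames = []
    for _, g in table.df.groupby("subject", sort=False):
        g = g.sort_values("ic")
        n_blocks = len(g) // k
        if n_blocks == 0:
            continue
        g = g.iloc[: n_blocks * k]
        block = np.repeat(np.arange(n_blocks), k)
        agg = g[num_cols].groupby(block).mean()
        agg["subject"] = g["subject"].iloc[0]
        agg["foot"] = "both"
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return StrideFeatureTable(
        df=out, feature_cols=table.feature_cols,
        meta={**table.meta, "averaged_over": k},
    )
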