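"""Gait event detection and temporal parameters.

The run is segmented into mid-swing to mid-swing cycles: mid-swings are the
positive peaks of the pitch-axis (FF z) angular velocity, found with a
minimum inter-peak spacing derived from a YIN cadence estimate over 10-s
sliding windows (5-s overlap).  Within each cycle the initial contact (IC)
and terminal contact (TC) are the two most prominent local minima of the
pitch rate, ordered in time; MinRot is the most static instant of stance,
the argmin of the angular-velocity norm between IC and TC.

Per step i over the merged two-foot IC sequence (steps alternate feet,
strides are same-foot IC to IC):

    CT_i  = TC_i   - IC_i        (contact time)
    FLT_i = IC_i+1 - TC_i        (flight time)
    SWT_i = IC_i+2 - TC_i        (swing time)
    STP_i = IC_i+1 - IC_i        (step duration)
    STR_i = IC_i+2 - IC_i        (stride duration)

Strides with STR outside [0.37, 2.5] s or FLT <= 0 are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "GaitCycleTable",
    "NoGaitPeriodicityError",
    "yin_period",
    "detect_midswing",
    "detect_ic_tc",
    "detect_minrot",
    "temporal_parameters",
    "remove_invalid_strides",
    "detect_gait_events",
]

STRIDE_MIN_S = 0.37
STRIDE_MAX_S = 2.5


class NoGaitPeriodicityError(ValueError):
    """YIN found no usable periodicity in the pitch angular velocity."""


@dataclass
class GaitCycleTable:
    """Per-step gait events and temporal parameters.

    ``df`` has one row per step (merged two-foot IC order) with columns:
    ``foot``, ``midswing_idx``, ``ic_idx``, ``tc_idx``, ``minrot_idx``,
    ``ic``, ``tc`` (seconds), ``ct``, ``flt``, ``swt``, ``stp``, ``str``,
    ``valid`` and ``reason``.
    """

    df: pd.DataFrame
    fs: float = 500.0
    rejections: dict = field(default_factory=dict)

    def valid(self) -> pd.DataFrame:
        return self.df[self.df.valid]

    @property
    def n_steps(self) -> int:
        return len(self.df)

    def for_foot(self, foot: str) -> pd.DataFrame:
        return self.df[self.df.foot == foot]


def _cmndf(frame: np.ndarray, max_lag: int) -> np.ndarray:
    """Cumulative-mean-normalized difference function of one frame."""
    w = frame.size
    f = np.fft.rfft(frame, 2 * w)
    ac = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    csum = np.cumsum(frame * frame)
    total = csum[-1]
    lags = np.arange(max_lag + 1)
    head = np.concatenate([[total], total - csum[lags[1:] - 1]])  # sum x_j^2, j>=lag
    tail = np.concatenate([[total], csum[w - lags[1:] - 1]])  # sum x_j^2, j<w-lag
    d = tail + head - 2 * ac
    d[0] = 0.0
    cum = np.cumsum(d[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.empty_like(d)
        dn[0] = 1.0
        dn[1:] = d[1:] * lags[1:] / np.where(cum > 0, cum, np.inf)
    return dn


def yin_period(
    x: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    hop_s: float = 5.0,
    threshold: float = 0.15,
    period_range: tuple[float, float] = (0.3, 2.5),
) -> tuple[np.ndarray, np.ndarray]:
    """YIN fundamental-period estimate over sliding windows.

    Returns ``(window_centers_s, periods_s)``.  Raises
    :class:`NoGaitPeriodicityError` when no window shows periodicity
    (the normalized difference never drops below 0.8).
    """
    x = np.asarray(x, dtype=float)
    w = int(window_s * fs)
    hop = int(hop_s * fs)
    if x.size < w:
        raise NoGaitPeriodicityError("signal shorter than one YIN window (10 s)")
    min_lag = max(int(period_range[0] * fs), 2)
    max_lag = min(int(period_range[1] * fs), w - 2)
    centers, periods = [], []
    for start in range(0, x.size - w + 1, hop):
        frame = x[start : start + w] - x[start : start + w].mean()
        if np.allclose(frame, 0.0):
            continue
        dn = _cmndf(frame, max_lag)
        seg = dn[min_lag : max_lag + 1]
        below = np.flatnonzero(seg < threshold)
        if below.size:
            tau = below[0] + min_lag
            while tau + 1 <= max_lag and dn[tau + 1] < dn[tau]:
                tau += 1
        else:
            tau = int(np.argmin(seg)) + min_lag
            if dn[tau] > 0.8:
                continue
        # parabolic lag refinement
        if 1 <= tau < dn.size - 1:
            y0, y1, y2 = dn[tau - 1], dn[tau], dn[tau + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            tau = tau + float(np.clip(shift, -1, 1))
        centers.append((start + w / 2) / fs)
        periods.append(tau / fs)
    if not periods:
        raise NoGaitPeriodicityError("no gait periodicity")
    return np.asarray(centers), np.asarray(periods)


def detect_midswing(
    omega_z: np.ndarray,
    fs: float,
    kappa: float = 0.5,
    yin_kwargs: dict | None = None,
) -> np.ndarray:
    """Mid-swing sample indices: positive pitch-rate peaks with a YIN prior.

    The YIN period estimate sets the minimum spacing ``kappa * period``
    between accepted peaks; peaks must be strict local maxima with positive
    value and non-negligible prominence.
    """
    omega_z = np.asarray(omega_z, dtype=float)
    _, periods = yin_period(omega_z, fs, **(yin_kwargs or {}))
    period = float(np.median(periods))
    distance = max(int(kappa * period * fs), 1)
    all_peaks, all_props = find_peaks(omega_z, height=0.0)
    if all_peaks.size == 0:
        return all_peaks
    # height gate against numerical ripple on quiet stance plateaus, set
    # from the tall swing peaks, then the cadence-derived spacing
    h_ref = np.percentile(all_props["peak_heights"], 95)
    peaks, _ = find_peaks(omega_z, distance=distance, height=0.3 * h_ref)
    return peaks


def detect_ic_tc(
    omega_z: np.ndarray,
    midswings: np.ndarray,
    prominence_frac: float = 0.05,
) -> pd.DataFrame:
    """IC and TC per mid-swing cycle: the two most prominent pitch-rate
    minima between consecutive mid-swings, ordered in time.

    Returns a DataFrame with ``midswing_idx``, ``ic_idx``, ``tc_idx`` and
    ``valid``/``reason`` (cycles missing two minima are flagged, not raised).
    """
    omega_z = np.asarray(omega_z, dtype=float)
    if len(midswings) < 2:
        raise ValueError("need at least 2 mid-swing indices")
    scale = np.ptp(omega_z)
    rows = []
    for a, b in zip(midswings[:-1], midswings[1:]):
        seg = omega_z[a : b + 1]
        mins, props = find_peaks(-seg, prominence=prominence_frac * scale)
        if mins.size < 2:
            rows.append(dict(midswing_idx=a, ic_idx=-1, tc_idx=-1, valid=False,
                             reason="missing minima"))
            continue
        top2 = mins[np.argsort(props["prominences"])[-2:]]
        ic, tc = np.sort(top2) + a
        rows.append(dict(midswing_idx=a, ic_idx=int(ic), tc_idx=int(tc), valid=True,
                         reason=""))
    return pd.DataFrame(rows)


def detect_minrot(gyr: np.ndarray, ic_idx: int, tc_idx: int) -> int:
    """Argmin of the angular-velocity norm over stance [IC, TC], earliest tie."""
    if tc_idx < ic_idx:
        raise ValueError("empty stance window (TC before IC)")
    norm = np.linalg.norm(np.atleast_2d(gyr)[ic_idx : tc_idx + 1], axis=1)
    return ic_idx + int(np.argmin(norm))


def temporal_parameters(steps: pd.DataFrame, fs: float) -> pd.DataFrame:
    """Temporal gait parameters per step from the merged two-foot IC order.

    ``steps`` must hold one row per step with ``foot``, ``ic_idx``,
    ``tc_idx`` (plus any event columns) ordered by IC.  The last one or two
    steps lack successors and are flagged ``incomplete``; two consecutive
    ICs from the same foot flag the affected step ``missed contralateral
    step``.
    """
    df = steps.sort_values("ic_idx").reset_index(drop=True).copy()
    n = len(df)
    ic = df.ic_idx.to_numpy(dtype=float)
    tc = df.tc_idx.to_numpy(dtype=float)
    ic1 = np.append(ic[1:], np.nan)  # IC_{i+1}
    ic2 = np.append(ic[2:], [np.nan, np.nan])  # IC_{i+2}
    df["ic"] = ic / fs
    df["tc"] = tc / fs
    df["ct"] = (tc - ic) / fs
    df["flt"] = (ic1 - tc) / fs
    df["swt"] = (ic2 - tc) / fs
    df["stp"] = (ic1 - ic) / fs
    df["str"] = (ic2 - ic) / fs
    if "valid" not in df:
        df["valid"] = True
        df["reason"] = ""
    incomplete = np.isnan(df["str"].to_numpy())
    df.loc[incomplete & df.valid, "reason"] = "incomplete"
    df.loc[incomplete, "valid"] = False
    feet = df.foot.to_numpy()
    same = np.flatnonzero(feet[:-1] == feet[1:])
    for i in same:
        for j in (i, i + 1):
            if df.at[j, "valid"]:
                df.at[j, "valid"] = False
                df.at[j, "reason"] = "missed contralateral step"
    return df


def remove_invalid_strides(table: GaitCycleTable) -> GaitCycleTable:
    """Flag strides outside [0.37, 2.5] s or without a flight phase.

    Bounds are inclusive.  Returns a new table; ``rejections`` counts each
    reason.
    """
    df = table.df.copy()
    was_valid = df.valid.to_numpy()
    strides = df["str"].to_numpy()
    flt = df["flt"].to_numpy()
    too_short = was_valid & (strides < STRIDE_MIN_S)
    too_long = was_valid & (strides > STRIDE_MAX_S)
    no_flight = was_valid & ~too_short & ~too_long & (flt <= 0)
    for mask, reason in ((too_short, "too short"), (too_long, "too long"),
                         (no_flight, "no flight")):
        df.loc[mask, "valid"] = False
        df.loc[mask, "reason"] = reason
    rejections = dict(table.rejections)
    rejections.update(
        {"too short": int(too_short.sum()), "too long": int(too_long.sum()),
         "no flight": int(no_flight.sum())}
    )
    return GaitCycleTable(df=df, fs=table.fs, rejections=rejections)


def detect_gait_events(
    recordings: dict,
    kappa: float = 0.5,
    prominence_frac: float = 0.05,
) -> GaitCycleTable:
    """Full event chain on a left/right pair of functional-frame recordings.

    Per foot: mid-swing peaks -> IC/TC minima -> MinRot; the per-foot
    cycles are then merged in IC order into the step table and the
    temporal parameters (CT, FLT, SWT, STP, STR) computed, followed by the
    stride validity filters.
    """
    frames = []
    fs = None
    for foot, rec in recordings.items():
        if rec.frame != "functional":
            raise ValueError(f"{foot} recording is not in the functional frame")
        fs = rec.fs
        ms = detect_midswing(rec.gyr[:, 2], fs, kappa=kappa)
        cyc = detect_ic_tc(rec.gyr[:, 2], ms, prominence_frac=prominence_frac)
        minrot = np.full(len(cyc), -1)
        for i, row in cyc.iterrows():
            if row.valid:
                minrot[i] = detect_minrot(rec.gyr, int(row.ic_idx), int(row.tc_idx))
        cyc["minrot_idx"] = minrot
        cyc.insert(0, "foot", foot)
        frames.append(cyc[cyc.valid | (cyc.reason != "")])
    merged = pd.concat(frames, ignore_index=True)
    merged = merged[merged.valid].reset_index(drop=True)
    df = temporal_parameters(merged, fs)
    table = GaitCycleTable(df=df, fs=fs)
    return remove_invalid_strides(table)
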