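"""GNSS reference-speed estimation.

Raw 10-Hz GNSS speed is turned into the reference signal ``v_ref`` in two
steps: outlier removal (speed outside 5-20 km/h, or per-sample accuracy
worse than 0.15 m/s) followed by smoothing -- a 0.5-s moving average on the
unevenly sampled survivors, linear interpolation back onto a uniform 10-Hz
grid, and a zero-phase 4th-order Butterworth low-pass at 0.25 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "GNSSTrack",
    "ReferenceSpeed",
    "filter_gnss_outliers",
    "smooth_resample",
    "lowpass_reference",
    "reference_speed_chain",
]

SPEED_MIN_KMH = 5.0
SPEED_MAX_KMH = 20.0
ACCURACY_MAX = 0.15  # m/s
KMH = 3.6  # m/s -> km/h


class EmptyReferenceError(ValueError):
    """All GNSS samples were rejected; no reference speed can be built."""


@dataclass
class GNSSTrack:
    """Time-stamped GNSS speed with per-sample accuracy estimates."""

    time: np.ndarray
    speed: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("GNSS time must be strictly increasing")
        if np.any(self.speed < 0):
            raise ValueError("GNSS speed must be non-negative")
        if np.any(self.accuracy < 0):
            raise ValueError("GNSS accuracy must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class ReferenceSpeed:
    """Uniformly sampled reference speed ``v_ref``."""

    time: np.ndarray
    v_ref: np.ndarray
    rate: float = 10.0
    valid: np.ndarray | None = None  # False inside long-gap intervals

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.v_ref = np.asarray(self.v_ref, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time.size, dtype=bool)

    def mean_over(self, t0: float, t1: float) -> float:
        """Mean v_ref over the half-open window [t0, t1); NaN if uncovered."""
        m = (self.time >= t0) & (self.time < t1) & self.valid
        if not m.any():
            return float("nan")
        return float(self.v_ref[m].mean())


def filter_gnss_outliers(
    track: GNSSTrack,
    speed_min_kmh: float = SPEED_MIN_KMH,
    speed_max_kmh: float = SPEED_MAX_KMH,
    accuracy_max: float = ACCURACY_MAX,
) -> tuple[GNSSTrack, np.ndarray, np.ndarray]:
    """Drop samples outside 5-20 km/h or with accuracy worse than 0.15 m/s.

    Returns ``(filtered_track, retained_idx, discarded_idx)``.  Raises
    :class:`EmptyReferenceError` when fewer than 2 samples survive
    (downstream interpolation needs at least two points).
    """
    kmh = track.speed * KMH
    keep = (kmh >= speed_min_kmh) & (kmh <= speed_max_kmh) & (
        track.accuracy <= accuracy_max
    )
    retained = np.flatnonzero(keep)
    discarded = np.flatnonzero(~keep)
    if retained.size < 2:
        raise EmptyReferenceError(
            f"only {retained.size} GNSS samples survive the outlier filters"
        )
    out = GNSSTrack(track.time[keep], track.speed[keep], track.accuracy[keep])
    return out, retained, discarded


def smooth_resample(
    track: GNSSTrack,
    window_s: float = 0.5,
    rate: float = 10.0,
    max_gap_s: float = 5.0,
) -> ReferenceSpeed:
    """Centered moving average on uneven samples, then uniform resampling.

    The moving average is a time-window mean of width ``window_s`` centered
    on each retained sample.  Linear interpolation follows, onto a uniform
    grid at ``rate`` Hz spanning the retained time range.  Grid samples that
    fall inside a gap longer than ``max_gap_s`` are flagged invalid rather
    than trusted.
    """
    if track.n_samples < 2:
        raise EmptyReferenceError("need at least 2 samples to resample")
    t, v = track.time, track.speed
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    c = np.cumsum(np.insert(v, 0, 0.0))
    smoothed = (c[hi] - c[lo]) / (hi - lo)

    dt = 1.0 / rate
    n = int(np.floor((t[-1] - t[0]) / dt)) + 1
    grid = t[0] + dt * np.arange(n)
    v_ref = np.interp(grid, t, smoothed)

    valid = np.ones(n, dtype=bool)
    gaps = np.diff(t)
    for j in np.flatnonzero(gaps > max_gap_s):
        valid[(grid > t[j]) & (grid < t[j + 1])] = False
    return ReferenceSpeed(time=grid, v_ref=v_ref, rate=rate, valid=valid)


def lowpass_reference(
    series: ReferenceSpeed,
    fc: float = 0.25,
    order: int = 4,
    out_rate: float | None = None,
) -> ReferenceSpeed:
    """Zero-phase 4th-order Butterworth at 0.25 Hz, optional down-sampling.

    ``out_rate`` defaults to keeping the input rate (the final down-sampled
    rate of the reference chain is configurable).
    """
    n_min = 3 * (2 * order + 1)
    if series.time.size < n_min:
        raise ValueError("reference series shorter than filter warm-up")
    sos = signal.butter(order, fc, btype="low", fs=series.rate, output="sos")
    v = signal.sosfiltfilt(sos, series.v_ref)
    time, valid, rate = series.time, series.valid.copy(), series.rate
    if out_rate is not None and out_rate < series.rate:
        step = int(round(series.rate / out_rate))
        time, v, valid = time[::step], v[::step], valid[::step]
        rate = series.rate / step
    return ReferenceSpeed(time=time, v_ref=v, rate=rate, valid=valid)


def reference_speed_chain(
    track: GNSSTrack,
    *,
    window_s: float = 0.5,
    rate: float = 10.0,
    max_gap_s: float = 5.0,
    fc: float = 0.25,
    out_rate: float | None = None,
    time_mask: tuple[float, float] | None = None,
) -> ReferenceSpeed:
    """Full raw-GNSS-to-v_ref chain: outlier filters, smoothing, low-pass.

    ``time_mask`` optionally restricts the track to an analysis interval
    (the stand-in for manual removal of rest and walking bouts).
    """
    if time_mask is not None:
        m = (track.time >= time_mask[0]) & (track.time <= time_mask[1])
        if m.sum() < 2:
            raise EmptyReferenceError("time mask leaves fewer than 2 samples")
        track = GNSSTrack(track.time[m], track.speed[m], track.accuracy[m])
    filtered, _, _ = filter_gnss_outliers(track)
    resampled = smooth_resample(filtered, window_s=window_s, rate=rate, max_gap_s=max_gap_s)
    return lowpass_reference(resampled, fc=fc, out_rate=out_rate)
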