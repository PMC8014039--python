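"""IMU pre-processing: low-pass filtering, functional-frame alignment, and
barometric slope estimation.

The foot *functional frame* (FF) has x longitudinal (toward the forefoot),
y vertical (up) and z mediolateral (to the subject's right).  Sensors are
physically strapped in an arbitrary *technical frame*; a rotation maps
technical to functional coordinates.  The rotation may be supplied (from an
external calibration) or estimated from a level-walking segment with
:func:`estimate_alignment_from_walk`.

Overground slope is derived from barometric pressure: pressure is converted
to altitude with the standard-atmosphere hypsometric formula, smoothed with
a 4-s moving average, down-sampled to 1 Hz, and differenced over 5-s spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

__all__ = [
    "IMURecording",
    "SlopeSeries",
    "lowpass_imu",
    "align_to_functional_frame",
    "estimate_alignment_from_walk",
    "altitude_from_pressure",
    "slope_from_altitude",
    "slope_to_grade",
]

#: standard-atmosphere sea-level pressure, hPa
P0_STANDARD = 1013.25
#: hypsometric scale height coefficient, m
HYPSOMETRIC_SCALE = 44330.0
#: hypsometric exponent (standard atmosphere)
HYPSOMETRIC_EXPONENT = 0.1903

GRAVITY = 9.81  # m/s^2


@dataclass
class IMURecording:
    """Synchronized per-foot inertial and barometric streams.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, uniform (nominally 500 Hz).
    acc : ndarray, shape (n, 3)
        Triaxial acceleration (specific force), m/s^2.
    gyr : ndarray, shape (n, 3)
        Triaxial angular velocity, rad/s (converted on construction if the
        recording declares deg/s).
    baro_time, baro : ndarray
        Barometric pressure stream, hPa, nominally 50 Hz.
    frame : str
        ``"technical"`` or ``"functional"``.
    foot : str
        ``"left"`` or ``"right"``.
    """

    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    baro_time: np.ndarray | None = None
    baro: np.ndarray | None = None
    frame: str = "technical"
    foot: str = "left"
    gyro_unit: str = "rad/s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        if self.acc.shape != (self.time.size, 3):
            raise ValueError("acc must have shape (n_samples, 3)")
        if self.gyr.shape != (self.time.size, 3):
            raise ValueError("gyr must have shape (n_samples, 3)")
        if self.gyro_unit == "deg/s":
            self.gyr = np.deg2rad(self.gyr)
            self.gyro_unit = "rad/s"
        elif self.gyro_unit != "rad/s":
            raise ValueError(f"unknown gyro unit {self.gyro_unit!r}")
        if self.baro is not None:
            self.baro = np.asarray(self.baro, dtype=float)
            self.baro_time = np.asarray(self.baro_time, dtype=float)

    @property
    def fs(self) -> float:
        """Sampling rate of the inertial streams, Hz."""
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class SlopeSeries:
    """Overground slope signal: altitude difference over 5-s spans.

    ``slope`` keeps the native unit of the differencing (metres of altitude
    change per 5 s); :func:`slope_to_grade` converts to a dimensionless
    grade given a speed.
    """

    time: np.ndarray
    slope: np.ndarray
    window_s: float = 5.0
    edge_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)


def _butter_filtfilt(x: np.ndarray, fs: float, fc: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def lowpass_imu(rec: IMURecording, fc: float = 50.0, order: int = 4) -> IMURecording:
    """Zero-phase 4th-order Butterworth low-pass on acceleration and gyro.

    The barometer stream is left untouched.  Raises ``ValueError`` when the
    stream is too short for the filter's warm-up (``filtfilt`` padding).
    """
    fs = rec.fs
    if rec.n_samples < 3 * (2 * 4 + 1):
        raise ValueError("stream shorter than filter warm-up")
    acc = _butter_filtfilt(rec.acc, fs, fc, order)
    gyr = _butter_filtfilt(rec.gyr, fs, fc, order)
    return replace(rec, acc=acc, gyr=gyr)


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or not np.isclose(
        np.linalg.det(R), 1.0, atol=tol
    ):
        raise ValueError("matrix is not a proper rotation (R^T R = I, det = +1)")
    return R


def align_to_functional_frame(rec: IMURecording, R: np.ndarray) -> IMURecording:
    """Rotate acceleration and angular velocity into the foot functional frame.

    ``R`` maps technical-frame vectors to functional-frame vectors
    (``v_FF = R @ v_tech``).  Must be a proper rotation to 1e-6.
    """
    R = _check_rotation(R)
    return replace(rec, acc=rec.acc @ R.T, gyr=rec.gyr @ R.T, frame="functional")


def estimate_alignment_from_walk(
    walk: IMURecording,
    static_window_s: float = 1.0,
    static_gyro_thresh: float = 0.1,
) -> np.ndarray:
    """Estimate the technical-to-functional rotation from a level segment.

    Simplified functional calibration: the vertical (FF y) axis is the mean
    specific-force direction over the most static window found (gravity
    points up through a resting foot); the mediolateral (FF z) axis is the
    dominant angular-velocity direction during movement (first principal
    component of the gyro samples), with the sign chosen so mid-swing pitch
    peaks come out positive; FF x completes the right-handed triad.

    Returns the 3x3 rotation ``R`` with ``v_FF = R @ v_tech``.
    """
    if walk.time[-1] - walk.time[0] < 10.0:
        raise ValueError("need at least 10 s of walking data for alignment")
    fs = walk.fs
    w = max(int(static_window_s * fs), 2)
    gnorm = np.linalg.norm(walk.gyr, axis=1)
    # most static window: minimum moving-average gyro norm
    kernel = np.ones(w) / w
    avg = np.convolve(gnorm, kernel, mode="valid")
    i0 = int(np.argmin(avg))
    if avg[i0] > static_gyro_thresh * max(gnorm.max(), 1.0):
        pass  # still proceed; threshold is only a sanity guide
    g_dir = walk.acc[i0 : i0 + w].mean(axis=0)
    g_norm = np.linalg.norm(g_dir)
    if g_norm < 1e-6:
        raise ValueError("no static window with a usable gravity direction found")
    y_axis = g_dir / g_norm

    moving = gnorm > np.percentile(gnorm, 75)
    if moving.sum() < 10:
        raise ValueError("no movement found for mediolateral axis estimation")
    G = walk.gyr[moving]
    # dominant rotation axis: first principal component of the gyro cloud
    _, s, vt = np.linalg.svd(G - G.mean(axis=0), full_matrices=False)
    if s[0] < 1e-9 or (s.size > 1 and s[0] < 2 * s[1] * 0.0 + 1e-12):
        raise ValueError("degenerate principal angular-velocity direction")
    z_axis = vt[0]
    # sign: the sustained mid-swing pitch lobe must come out positive.  The
    # contact-event dips can be deeper but are brief, so compare the time
    # spent beyond a threshold on each side rather than the extreme values.
    proj = G @ z_axis
    thresh = 0.3 * np.abs(proj).max()
    if (proj > thresh).mean() < (proj < -thresh).mean():
        z_axis = -z_axis
    # orthogonalize z against y, then complete the triad
    z_axis = z_axis - (z_axis @ y_axis) * y_axis
    nz = np.linalg.norm(z_axis)
    if nz < 1e-6:
        raise ValueError("mediolateral axis degenerate with gravity direction")
    z_axis /= nz
    x_axis = np.cross(y_axis, z_axis)
    # rows of R are the FF axes expressed in the technical frame
    R = np.vstack([x_axis, y_axis, z_axis])
    return _check_rotation(R, tol=1e-6)


def altitude_from_pressure(
    baro_time: np.ndarray,
    pressure: np.ndarray,
    p0: float = P0_STANDARD,
    smooth_s: float = 4.0,
    out_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Barometric pressure (hPa) to altitude (m) at 1 Hz.

    Applies the standard-atmosphere hypsometric formula
    ``h = 44330 * (1 - (p/p0)**0.1903)``, a 4-s moving average, and
    down-sampling to ``out_rate``.
    """
    pressure = np.asarray(pressure, dtype=float)
    baro_time = np.asarray(baro_time, dtype=float)
    if np.any(pressure <= 0):
        raise ValueError("non-positive pressure")
    alt = HYPSOMETRIC_SCALE * (1.0 - (pressure / p0) ** HYPSOMETRIC_EXPONENT)
    fs = 1.0 / float(np.median(np.diff(baro_time))) if baro_time.size > 1 else 1.0
    w = max(int(round(smooth_s * fs)), 1)
    if w > 1:
        # centered moving average; edges use shrinking windows
        c = np.cumsum(np.insert(alt, 0, 0.0))
        half = w // 2
        n = alt.size
        lo = np.clip(np.arange(n) - half, 0, n)
        hi = np.clip(np.arange(n) + half + 1, 0, n)
        alt = (c[hi] - c[lo]) / (hi - lo)
    t_out = np.arange(baro_time[0], baro_time[-1] + 1e-9, 1.0 / out_rate)
    alt_out = np.interp(t_out, baro_time, alt)
    return t_out, alt_out


def slope_from_altitude(
    alt_time: np.ndarray, alt: np.ndarray, window_s: float = 5.0
) -> SlopeSeries:
    """Slope as the altitude difference between samples spaced ``window_s`` apart.

    Centered differencing: ``s(t) = alt(t + w/2) - alt(t - w/2)``.  Edge
    samples fall back to one-sided differences and are flagged.
    """
    alt_time = np.asarray(alt_time, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if alt_time[-1] - alt_time[0] < window_s:
        raise ValueError(f"altitude series shorter than {window_s} s")
    half = window_s / 2.0
    fwd = np.interp(np.clip(alt_time + half, alt_time[0], alt_time[-1]), alt_time, alt)
    bwd = np.interp(np.clip(alt_time - half, alt_time[0], alt_time[-1]), alt_time, alt)
    span = np.clip(alt_time + half, alt_time[0], alt_time[-1]) - np.clip(
        alt_time - half, alt_time[0], alt_time[-1]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(span > 0, (fwd - bwd) * (window_s / np.maximum(span, 1e-12)), 0.0)
    edge = (alt_time - half < alt_time[0]) | (alt_time + half > alt_time[-1])
    return SlopeSeries(time=alt_time, slope=s, window_s=window_s, edge_flag=edge)


def slope_to_grade(slope: SlopeSeries, speed_m_s: np.ndarray | float) -> np.ndarray:
    """Convert altitude-per-5-s slope to a dimensionless grade at a given speed."""
    dist = np.asarray(speed_m_s, dtype=float) * slope.window_s
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dist > 0, slope.slope / dist, np.nan)


def mounting_rotation(rotvec_deg: tuple[float, float, float]) -> np.ndarray:
    """Convenience: rotation matrix from a rotation vector given in degrees."""
    return Rotation.from_rotvec(np.deg2rad(rotvec_deg)).as_matrix()
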