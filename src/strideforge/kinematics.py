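"""Foot orientation, gravity removal and drift-corrected velocity.

Strapdown chain per foot: orientation is anchored at each stride's MinRot
instant (the most static sample of stance) where the accelerometer reads
gravity -- tilt is taken from the mean specific-force direction over a
20-ms window and the attitude is propagated between anchors by body-rate
quaternion integration.  Gravity (g = [0, 0, 9.81] m/s^2 in the global
frame, z up) is removed from the rotated acceleration, which is then
integrated with the trapezoidal rule from each anchor (v(MinRot) := 0).
The residual velocity observed at the next anchor is the accumulated drift;
a linear-in-time correction is subtracted across the interval so both
anchors read exactly zero (the standard zero-velocity-update de-drift).
The corrected global-frame velocity is also reported rotated back into the
foot functional frame (``v_foot``).

The anchor attitude fixes tilt only; heading is left at zero.  Pitch angle
and all speed norms used downstream are invariant to heading, so the
simplification costs nothing for speed estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from strideforge.preprocess import GRAVITY, IMURecording

__all__ = [
    "FootStateSeries",
    "estimate_orientation",
    "gravity_free_acceleration",
    "integrate_with_drift_reset",
    "pitch_from_orientation",
    "pitch_at_ic",
    "direct_step_speed",
    "foot_kinematics",
]

G_VEC = np.array([0.0, 0.0, GRAVITY])


@dataclass
class FootStateSeries:
    """Per-sample foot kinematic state for one foot."""

    time: np.ndarray
    rot: Rotation  # FF -> GF, length n
    a_gf: np.ndarray  # gravity-free acceleration, m/s^2
    v_gf: np.ndarray  # drift-corrected velocity in GF, m/s
    v_ff: np.ndarray  # the same velocity expressed in FF (v_foot), m/s
    theta: np.ndarray  # pitch angle, rad
    integrated: np.ndarray  # bool mask: samples covered by anchor intervals
    anchors: np.ndarray  # MinRot sample indices used
    foot: str = "left"
    excluded_anchors: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.v_gf, axis=1)


def _tilt_rotation(direction: np.ndarray) -> Rotation:
    """Minimal rotation taking ``direction`` to the global up axis."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    c = float(d @ z)
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle)


def _cumulative_rotation(deltas: Rotation) -> Rotation:
    """Prefix composition r_k = d_0 * d_1 * ... * d_k, vectorized by doubling."""
    q = deltas.as_quat().copy()
    n = q.shape[0]
    shift = 1
    while shift < n:
        a = Rotation.from_quat(q[: n - shift])
        b = Rotation.from_quat(q[shift:])
        q[shift:] = (a * b).as_quat()
        shift *= 2
    return Rotation.from_quat(q)


def _propagate(rot0: Rotation, gyr: np.ndarray, dt: float, forward: bool) -> Rotation:
    """Body-rate quaternion integration from an anchor attitude.

    ``gyr`` are the body rates over the interval (anchor sample first when
    forward, anchor sample last when backward)."""
    if gyr.shape[0] <= 1:
        return Rotation.concatenate([rot0] * max(gyr.shape[0], 1))
    if forward:
        w_mid = 0.5 * (gyr[:-1] + gyr[1:]) * dt
        steps = Rotation.from_rotvec(w_mid)
        cum = _cumulative_rotation(steps)
        out = Rotation.concatenate([rot0, rot0 * cum])
    else:
        w_mid = 0.5 * (gyr[:-1] + gyr[1:]) * dt
        rev = Rotation.from_rotvec(-w_mid[::-1])
        cum = _cumulative_rotation(rev)
        out = Rotation.concatenate([rot0, rot0 * cum])
        out = Rotation.from_quat(out.as_quat()[::-1])
    return out


def estimate_orientation(
    rec: IMURecording,
    cycles: pd.DataFrame,
    anchor_window_s: float = 0.02,
    anchor_tolerance: float = 0.2,
) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Foot orientation (FF -> GF) anchored at each stride's MinRot.

    At each MinRot the mean specific force over a centered 20-ms window
    gives the gravity direction; anchors whose specific-force norm deviates
    from 9.81 m/s^2 by more than ``anchor_tolerance`` (20 %) are flagged
    unreliable and skipped.  Between anchors the attitude follows gyroscope
    integration; before the first and after the last anchor it is
    propagated outward.

    Returns ``(rotations, anchor_indices, excluded_anchor_indices)``.
    """
    if rec.frame != "functional":
        raise ValueError("recording must be in the functional frame")
    fs = rec.fs
    dt = 1.0 / fs
    half = max(int(anchor_window_s * fs / 2), 1)
    n = rec.n_samples

    raw_anchors = np.sort(
        cycles.loc[cycles.minrot_idx >= 0, "minrot_idx"].to_numpy(dtype=int)
    )
    raw_anchors = np.unique(raw_anchors)
    anchors, excluded, tilts = [], [], []
    for m in raw_anchors:
        win = rec.acc[max(m - half, 0) : min(m + half + 1, n)]
        mean_f = win.mean(axis=0)
        if abs(np.linalg.norm(mean_f) - GRAVITY) > anchor_tolerance * GRAVITY:
            excluded.append(m)
            continue
        anchors.append(m)
        tilts.append(_tilt_rotation(mean_f))
    if not anchors:
        raise ValueError("no reliable MinRot anchors found")
    anchors = np.asarray(anchors, dtype=int)

    quats = np.empty((n, 4))
    # before the first anchor: integrate backward
    first, last = anchors[0], anchors[-1]
    back = _propagate(tilts[0], rec.gyr[: first + 1], dt, forward=False)
    quats[: first + 1] = back.as_quat()
    for k in range(len(anchors) - 1):
        a, b = anchors[k], anchors[k + 1]
        seg = _propagate(tilts[k], rec.gyr[a : b + 1], dt, forward=True)
        quats[a : b + 1] = seg.as_quat()
    fwd = _propagate(tilts[-1], rec.gyr[last:], dt, forward=True)
    quats[last:] = fwd.as_quat()
    return Rotation.from_quat(quats), anchors, np.asarray(excluded, dtype=int)


def gravity_free_acceleration(rec: IMURecording, rot: Rotation) -> np.ndarray:
    """Rotate FF acceleration into GF and remove gravity: R(q) a_FF - g."""
    return rot.apply(rec.acc) - G_VEC


def integrate_with_drift_reset(
    a_gf: np.ndarray,
    time: np.ndarray,
    anchors: np.ndarray,
    cycles: pd.DataFrame | None = None,
    mode: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoidal velocity integration with per-stride ZUPT drift removal.

    Within each anchor-to-anchor interval the velocity is the trapezoidal
    cumulative integral starting at zero; the residual observed at the far
    anchor is removed by a correction linear in time, so the velocity is
    exactly zero at every anchor.  ``mode="clamp"`` additionally zeroes the
    velocity between each MinRot and the stance's TC (the literal stance
    reset), requiring ``cycles`` for the TC indices.

    Samples outside the first/last anchor are left at zero and reported as
    not integrated.
    """
    if mode not in ("linear", "clamp"):
        raise ValueError("mode must be 'linear' or 'clamp'")
    n = a_gf.shape[0]
    v = np.zeros((n, 3))
    integrated = np.zeros(n, dtype=bool)
    if anchors.size < 2:
        return v, integrated
    dt = np.diff(time)
    incr = 0.5 * (a_gf[1:] + a_gf[:-1]) * dt[:, None]
    for a, b in zip(anchors[:-1], anchors[1:]):
        raw = np.vstack([np.zeros(3), np.cumsum(incr[a:b], axis=0)])
        drift = raw[-1]
        frac = (time[a : b + 1] - time[a]) / (time[b] - time[a])
        v[a : b + 1] = raw - frac[:, None] * drift
        integrated[a : b + 1] = True
    if mode == "clamp" and cycles is not None:
        for _, row in cycles.iterrows():
            m, tc = int(row.minrot_idx), int(row.tc_idx)
            if 0 <= m < tc <= n - 1:
                v[m : tc + 1] = 0.0
    return v, integrated


def pitch_from_orientation(rot: Rotation) -> np.ndarray:
    """Pitch angle: arcsin of the GF-z component of the rotated FF x-axis.

    Positive pitch = toes above the heel line (rear-foot landing when taken
    at IC)."""
    x_gf = rot.apply(np.array([1.0, 0.0, 0.0]))
    return np.arcsin(np.clip(np.atleast_2d(x_gf)[:, 2], -1.0, 1.0))


def pitch_at_ic(theta: np.ndarray, cycles: pd.DataFrame) -> np.ndarray:
    """Pitch angle at each cycle's IC (NaN for invalid cycles)."""
    out = np.full(len(cycles), np.nan)
    for i, idx in enumerate(cycles.ic_idx.to_numpy(dtype=int)):
        if idx >= 0:
            out[i] = theta[idx]
    return out


def direct_step_speed(
    state: FootStateSeries,
    cycles: pd.DataFrame,
    mode: str = "norm",
) -> np.ndarray:
    """Per-step speed from the drift-corrected foot velocity.

    ``mode="norm"`` (default): mean of ||v_foot|| over the stride window
    [IC_i, IC_i+2).  ``mode="forward"``: mean of the GF forward component.
    The norm variant slightly overestimates on clean data because the foot
    path is longer than its displacement; the forward variant is exact on
    drift-free signals.  Incomplete strides yield NaN.
    """
    fs = 1.0 / float(np.median(np.diff(state.time)))
    sig = np.linalg.norm(state.v_gf, axis=1) if mode == "norm" else state.v_gf[:, 0]
    out = np.full(len(cycles), np.nan)
    ics = cycles.ic_idx.to_numpy(dtype=int)
    strs = cycles["str"].to_numpy(dtype=float)
    valid = cycles.valid.to_numpy(dtype=bool)
    for i, (ic, dur, ok) in enumerate(zip(ics, strs, valid)):
        if not ok or not np.isfinite(dur):
            continue
        end = ic + int(round(dur * fs))
        if end > sig.size:
            continue
        win = slice(ic, end)
        if not state.integrated[win].all():
            continue
        out[i] = float(sig[win].mean())
    return out


def foot_kinematics(
    rec: IMURecording,
    foot_cycles: pd.DataFrame,
    mode: str = "linear",
) -> FootStateSeries:
    """Full spatial chain for one foot: orientation, gravity removal,
    drift-corrected integration, pitch."""
    rot, anchors, excluded = estimate_orientation(rec, foot_cycles)
    a_gf = gravity_free_acceleration(rec, rot)
    v_gf, integrated = integrate_with_drift_reset(
        a_gf, rec.time, anchors, cycles=foot_cycles, mode=mode
    )
    v_ff = rot.apply(v_gf, inverse=True)
    theta = pitch_from_orientation(rot)
    return FootStateSeries(
        time=rec.time, rot=rot, a_gf=a_gf, v_gf=v_gf, v_ff=v_ff, theta=theta,
        integrated=integrated, anchors=anchors, foot=rec.foot,
        excluded_anchors=excluded,
    )
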