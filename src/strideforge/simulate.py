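"""Synthetic running-gait simulator with exact ground truth.

Generates per-foot IMU streams (500 Hz), barometric pressure (50 Hz) and a
GNSS speed track (10 Hz) for a commanded speed/slope profile, together with
the exact pre-noise ground truth (foot velocity, orientation, gait events,
per-stride speed labels).

The foot trajectory is built stride by stride: during stance the foot is
exactly stationary at ground level (providing the zero-velocity windows the
drift correction assumes); during swing it follows a minimum-jerk forward
arc with a raised-cosine vertical lift, reaching the next stance point so
the commanded per-stride speed is enforced by construction.  The sagittal
pitch rate is a sum of smooth lobes -- a negative lobe at each initial
contact (foot slap), a negative lobe at each terminal contact (push-off
plantarflexion) and a positive lobe peaking at mid-swing -- so the gait
event detector's landmarks exist by construction, and pitch angle has a
closed form (the lobes integrate analytically).

Accelerometer output is the exact specific force: the second derivative of
the trajectory plus gravity (g = 9.81 m/s^2, up), rotated into the foot
functional frame by the planted orientation; the gyroscope carries the
planted pitch rate on the mediolateral (z) axis.

Frames: global frame (GF) x forward, z up, y = z cross x (left); foot
functional frame (FF) x longitudinal, y up, z mediolateral right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from strideforge.gnss import GNSSTrack
from strideforge.preprocess import (
    GRAVITY,
    HYPSOMETRIC_EXPONENT,
    HYPSOMETRIC_SCALE,
    P0_STANDARD,
    IMURecording,
)

__all__ = [
    "Subject",
    "NoiseSpec",
    "SyntheticScenario",
    "GroundTruth",
    "simulate_session",
    "inject_gnss_outliers",
    "default_cadence",
    "default_duty_factor",
    "make_cohort",
]

#: FF axes expressed in GF at zero pitch: x->x, y->z(up), z->-y (right = -left)
R_BASE = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])

#: amplitude of the foot-slap pitch-rate dip at initial contact, rad/s
IMPACT_DIP = 10.0


def default_cadence(speed: float) -> float:
    """Stride frequency (Hz) as a function of running speed (m/s).

    Linear map calibrated to typical distance-running values: ~1.28 Hz at
    1.4 m/s rising to ~1.52 Hz at 5.4 m/s.
    """
    return 1.2 + 0.06 * speed


def default_duty_factor(speed: float) -> float:
    """Contact-time fraction of the stride as a function of speed (m/s).

    Decreases with speed (0.42 at 3 m/s); clipped so a flight phase always
    exists (duty factor < 0.5 guarantees FLT > 0).
    """
    return float(np.clip(0.42 - 0.04 * (speed - 3.0), 0.20, 0.495))


@dataclass
class Subject:
    """Anthropometrics plus the per-subject gait-style offset.

    ``speed_offset`` (m/s) shifts the speed at which the cadence and
    duty-factor maps are evaluated, so two subjects running at the same
    speed show different stride frequency / stride length trade-offs --
    the inter-subject heterogeneity a generic model cannot absorb and a
    personalized model can.
    """

    height: float = 1.75  # m
    weight: float = 70.0  # kg
    gender: int = 0  # 0 male, 1 female
    age: float = 35.0  # years
    speed_offset: float = 0.0  # m/s
    subject_id: str = "S00"


@dataclass
class NoiseSpec:
    """Sensor noise configuration (zero everything for exact sessions)."""

    acc_density: float = 0.02  # m/s^2/sqrt(Hz)
    gyro_density: float = 0.005  # rad/s/sqrt(Hz)
    baro_std: float = 0.03  # hPa per sample
    gnss_speed_std: float = 0.1  # m/s per sample
    gnss_outlier_rate: float = 0.0

    def validate(self) -> None:
        for name in ("acc_density", "gyro_density", "baro_std", "gnss_speed_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise.{name} must be >= 0")
        if not 0 <= self.gnss_outlier_rate < 1:
            raise ValueError("noise.gnss_outlier_rate must be in [0, 1)")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticScenario:
    """Full description of one simulated running session."""

    duration: float = 60.0  # s of running
    speed_profile: Callable[[float], float] | float = 3.0  # m/s
    slope_profile: Callable[[float], float] | float = 0.0  # grade (dimensionless)
    cadence_model: Callable[[float], float] = default_cadence
    duty_factor_model: Callable[[float], float] = default_duty_factor
    subject: Subject = field(default_factory=Subject)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    fs_imu: float = 500.0
    fs_baro: float = 50.0
    fs_gnss: float = 10.0
    standing_time: float = 2.0  # s of quiet standing before the run
    theta_landing: float = np.deg2rad(10.0)  # pitch at IC (+: rearfoot)
    theta_toeoff: float = np.deg2rad(-20.0)  # pitch at TC
    swing_lift: float = 0.10  # m apex of the foot arc
    baseline_altitude: float = 400.0  # m
    mounting_rotation: np.ndarray | None = None  # tech->FF rotation to recover
    #: fraction of the swing-phase translational acceleration the
    #: accelerometer fails to measure (mean and per-stride STD).  Zero by
    #: default (ideal sensing); positive values emulate the flight-phase
    #: observability loss that biases strapdown foot speed on real feet.
    flight_error_mean: float = 0.0
    flight_error_std: float = 0.0

    def speed_at(self, t: float) -> float:
        if callable(self.speed_profile):
            return float(self.speed_profile(t))
        return float(self.speed_profile)

    def grade_at(self, t: float) -> float:
        if callable(self.slope_profile):
            return float(self.slope_profile(t))
        return float(self.slope_profile)

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        self.noise.validate()
        probe = np.linspace(self.standing_time, self.standing_time + self.duration, 25)
        for t in probe:
            v = self.speed_at(t)
            if not 0 < v < 20:
                raise ValueError("speed_profile must be positive and bounded during running")
            veff = v + self.subject.speed_offset
            f = self.cadence_model(veff)
            if f <= 0:
                raise ValueError("cadence_model must be positive")
            df = self.duty_factor_model(veff)
            if not 0 < df < 1:
                raise ValueError("duty_factor_model must lie in (0, 1)")
        if self.flight_error_mean < 0 or self.flight_error_std < 0:
            raise ValueError("flight_error_mean/std must be >= 0")


@dataclass
class GroundTruth:
    """Exact (pre-noise) state of the simulated session."""

    time: np.ndarray  # IMU grid, s
    speed: np.ndarray  # per-sample overground speed, m/s (0 while standing)
    vel_gf: dict  # foot -> (n, 3) exact foot velocity in GF, m/s
    pitch: dict  # foot -> (n,) pitch angle, rad
    orientation: dict  # foot -> scipy Rotation (FF->GF), length n
    events: dict  # foot -> {"ic", "tc", "midswing", "minrot"} arrays of times
    static_windows: dict  # foot -> (K, 2) [start, end] of exact zero-vel+zero-rate
    strides: pd.DataFrame  # per-stride: foot, ic, tc, next_ic, duration, label, grade
    subject: Subject = field(default_factory=Subject)

    def stride_labels(self, foot: str) -> np.ndarray:
        return self.strides.loc[self.strides.foot == foot, "label"].to_numpy()


# ----------------------------------------------------------------------------
# pitch-rate lobes: a * cos^2(pi (t - c) / w) on |t - c| < w/2
# ----------------------------------------------------------------------------


def _add_lobe(t, omega, theta, c, w, a):
    """Accumulate one cos^2 pitch-rate lobe and its exact integral."""
    i0, i1 = np.searchsorted(t, (c - w / 2, c + w / 2))
    u = np.pi * (t[i0:i1] - c) / w
    omega[i0:i1] += a * np.cos(u) ** 2
    theta[i0:i1] += a * w / 4 + a * (w / np.pi) * (u / 2 + np.sin(2 * u) / 4)
    theta[i1:] += a * w / 2


def _min_jerk(tau):
    """Minimum-jerk unit ramp and its first two derivatives in unit time."""
    m = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    dm = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    ddm = 60 * tau - 180 * tau**2 + 120 * tau**3
    return m, dm, ddm


def _plan_foot(ics, scenario: SyntheticScenario, x0: float, alt0: float):
    """Stance schedule for one foot given its IC times.

    Returns (stride table rows, stance positions p[k] = (x, alt))."""
    delta = scenario.subject.speed_offset
    rows = []
    pos = [(x0, alt0)]
    for k in range(len(ics) - 1):
        t_ic, t_next = ics[k], ics[k + 1]
        T = t_next - t_ic
        v = scenario.speed_at(t_ic)
        g = scenario.grade_at(t_ic)
        ct = scenario.duty_factor_model(v + delta) * T
        L = v * T  # along-path stride length
        dx = L / np.sqrt(1 + g * g)
        dalt = g * dx
        x, alt = pos[-1]
        pos.append((x + dx, alt + dalt))
        rows.append(
            dict(ic=t_ic, tc=t_ic + ct, next_ic=t_next, duration=T, ct=ct,
                 label=L / T, grade=g)
        )
    return rows, pos


def _foot_signals(t, rows, pos, scenario: SyntheticScenario):
    """Exact position/velocity/acceleration + pitch for one foot."""
    n = t.size
    p = np.zeros((n, 3))  # columns: x (forward), alt (up), lateral handled outside
    v = np.zeros((n, 2))
    a = np.zeros((n, 2))
    omega = np.zeros(n)
    theta = np.zeros(n)
    lift = scenario.swing_lift

    # static before the first toe-off
    p[:, 0], p[:, 1] = pos[0]

    th_run = 0.0  # running pitch value at the current lobe boundary
    for k, row in enumerate(rows):
        tc, next_ic = row["tc"], row["next_ic"]
        S = next_ic - tc  # swing duration
        i0, i1 = np.searchsorted(t, (tc, next_ic))
        tau = (t[i0:i1] - tc) / S
        m, dm, ddm = _min_jerk(tau)
        x_a, alt_a = pos[k]
        x_b, alt_b = pos[k + 1]
        dx, dalt = x_b - x_a, alt_b - alt_a
        # lift bump 64 h (tau (1-tau))^3: zero velocity AND acceleration at
        # both swing ends, so the planted acceleration is continuous
        q = tau * (1 - tau)
        zl = 64 * lift * q**3
        dzl = 192 * lift * q**2 * (1 - 2 * tau)
        ddzl = 384 * lift * q * ((1 - 2 * tau) ** 2 - q)
        p[i0:i1, 0] = x_a + dx * m
        p[i0:i1, 1] = alt_a + dalt * m + zl
        v[i0:i1, 0] = dx * dm / S
        v[i0:i1, 1] = dalt * dm / S + dzl / S
        a[i0:i1, 0] = dx * ddm / S**2
        a[i0:i1, 1] = dalt * ddm / S**2 + ddzl / S**2
        # after the swing the foot rests at the new stance point
        p[i1:, 0], p[i1:, 1] = x_b, alt_b

        # pitch-rate lobes for this stride.  The landing is a fixed negative
        # impact dip centered exactly at IC (the detector's landmark,
        # independent of foot-strike style) followed by a recovery lobe that
        # settles the pitch to zero by mid-stance; push-off is a negative
        # lobe at TC reaching theta_toeoff; the swing lobe closes the loop
        # with a positive mid-swing peak.
        th_l, th_t = scenario.theta_landing, scenario.theta_toeoff
        a_imp = -IMPACT_DIP
        w_ic = min(0.15 * row["ct"], 0.3 * S)
        w_rec = 0.35 * row["ct"]  # slow heel/forefoot settle after landing
        w_tc = min(0.25 * row["ct"], 0.45 * S)
        w_ms = 0.4 * S
        if k > 0:  # the session starts from flat standing: no lobes at the first IC
            _add_lobe(t, omega, theta, row["ic"], w_ic, a_imp)
            th_run += a_imp * w_ic / 2
            # recovery settles the pitch to exactly zero by mid-stance, so
            # the quiet window reads pure gravity along the foot vertical
            a_rec = -th_run * 2 / w_rec
            _add_lobe(t, omega, theta, row["ic"] + (w_ic + w_rec) / 2, w_rec, a_rec)
            th_run = 0.0
        _add_lobe(t, omega, theta, tc, w_tc, 4 * th_t / w_tc)
        th_run += 2 * th_t
        ms = tc + S / 2
        # swing lobe targets the pre-landing pitch the next impact expects
        th_pre = th_l - a_imp * w_ic / 4
        a_ms = (th_pre - th_run) * 2 / w_ms
        _add_lobe(t, omega, theta, ms, w_ms, a_ms)
        th_run = th_pre
    # closing landing lobes of the final stride bring the foot to flat rest
    if rows:
        last = rows[-1]
        S_last = last["next_ic"] - last["tc"]
        w_ic = min(0.15 * last["ct"], 0.3 * S_last)
        w_rec = 0.35 * last["ct"]
        a_imp = -IMPACT_DIP
        _add_lobe(t, omega, theta, last["next_ic"], w_ic, a_imp)
        th_run += a_imp * w_ic / 2
        _add_lobe(t, omega, theta, last["next_ic"] + (w_ic + w_rec) / 2, w_rec,
                  -th_run * 2 / w_rec)
    return p, v, a, omega, theta


def _events_for(rows, last_ic):
    ics = np.array([r["ic"] for r in rows] + [last_ic])
    tcs = np.array([r["tc"] for r in rows])
    mids = np.array([(r["tc"] + r["next_ic"]) / 2 for r in rows])
    minrot = (ics[:-1] + tcs) / 2
    return dict(ic=ics, tc=tcs, midswing=mids, minrot=minrot)


def _static_windows(rows):
    out = []
    for k, r in enumerate(rows):
        S = r["next_ic"] - r["tc"]
        w_ic = min(0.15 * r["ct"], 0.3 * S)
        w_rec = 0.35 * r["ct"]
        w_tc = min(0.25 * r["ct"], 0.45 * S)
        start = r["ic"] + (w_ic / 2 + w_rec if k > 0 else 0.0)
        end = r["tc"] - w_tc / 2
        out.append((start, end))
    return np.array(out)


def simulate_session(
    scenario: SyntheticScenario,
) -> tuple[dict[str, IMURecording], GNSSTrack, GroundTruth]:
    """Simulate one running session.

    Returns ``(recordings, gnss_track, ground_truth)`` where ``recordings``
    maps ``"left"``/``"right"`` to :class:`IMURecording` (in the technical
    frame when a mounting rotation is configured, else already functional).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    fs = scenario.fs_imu
    t_end = scenario.standing_time + scenario.duration + 1.0
    t = np.arange(0.0, t_end, 1.0 / fs)

    # left-foot IC schedule from the cadence map
    delta = scenario.subject.speed_offset
    ics_l = [scenario.standing_time]
    while True:
        t_ic = ics_l[-1]
        f = scenario.cadence_model(scenario.speed_at(t_ic) + delta)
        t_next = t_ic + 1.0 / f
        if t_next > scenario.standing_time + scenario.duration:
            break
        ics_l.append(t_next)
    if len(ics_l) < 4:
        raise ValueError("duration too short: fewer than 3 strides")
    ics_l = np.array(ics_l)
    ics_r = (ics_l[:-1] + ics_l[1:]) / 2

    rows_l, pos_l = _plan_foot(ics_l, scenario, x0=0.0, alt0=scenario.baseline_altitude)
    # right foot starts half a stride ahead
    g0 = scenario.grade_at(ics_l[0])
    dx_half = (pos_l[1][0] - pos_l[0][0]) / 2
    rows_r, pos_r = _plan_foot(
        ics_r, scenario, x0=dx_half, alt0=scenario.baseline_altitude + g0 * dx_half
    )

    lateral = {"left": 0.10, "right": -0.10}
    recordings: dict[str, IMURecording] = {}
    vel_gf: dict[str, np.ndarray] = {}
    pitch: dict[str, np.ndarray] = {}
    orientation: dict[str, Rotation] = {}
    events: dict[str, dict] = {}
    static_w: dict[str, np.ndarray] = {}
    stride_frames = []

    acc_std = scenario.noise.acc_density * np.sqrt(fs / 2)
    gyr_std = scenario.noise.gyro_density * np.sqrt(fs / 2)

    for foot, rows, pos, ics in (
        ("left", rows_l, pos_l, ics_l),
        ("right", rows_r, pos_r, ics_r),
    ):
        p2, v2, a2, om, th = _foot_signals(t, rows, pos, scenario)
        # GF vectors: x forward, y lateral (constant), z up
        v_gf = np.column_stack([v2[:, 0], np.zeros_like(t), v2[:, 1]])
        a_gf = np.column_stack([a2[:, 0], np.zeros_like(t), a2[:, 1]])
        a_meas = a_gf
        if scenario.flight_error_mean > 0 or scenario.flight_error_std > 0:
            # per-stride loss of swing-phase translational observability
            a_meas = a_gf.copy()
            for r in rows:
                i0, i1 = np.searchsorted(t, (r["tc"], r["next_ic"]))
                kappa = float(np.clip(
                    rng.normal(scenario.flight_error_mean, scenario.flight_error_std),
                    0.0, 0.5,
                ))
                a_meas[i0:i1] *= 1.0 - kappa
        f_gf = a_meas + np.array([0.0, 0.0, GRAVITY])  # specific force
        # into FF: f_FF = Rz(theta)^T (R_base^T f_GF)
        u = f_gf @ R_BASE  # == R_BASE.T applied row-wise
        cth, sth = np.cos(th), np.sin(th)
        f_ff = np.column_stack(
            [cth * u[:, 0] + sth * u[:, 1], -sth * u[:, 0] + cth * u[:, 1], u[:, 2]]
        )
        gyr_ff = np.column_stack([np.zeros_like(t), np.zeros_like(t), om])

        acc_out, gyr_out = f_ff, gyr_ff
        frame = "functional"
        if scenario.mounting_rotation is not None:
            R = np.asarray(scenario.mounting_rotation, dtype=float)
            acc_out, gyr_out = acc_out @ R, gyr_out @ R  # v_tech = R^T v_FF
            frame = "technical"
        if acc_std > 0:
            acc_out = acc_out + rng.normal(0.0, acc_std, acc_out.shape)
        if gyr_std > 0:
            gyr_out = gyr_out + rng.normal(0.0, gyr_std, gyr_out.shape)

        # barometer: altitude of the foot (plus swing lift) at 50 Hz
        t_baro = np.arange(0.0, t_end, 1.0 / scenario.fs_baro)
        alt_baro = np.interp(t_baro, t, p2[:, 1])
        pres = P0_STANDARD * (1.0 - alt_baro / HYPSOMETRIC_SCALE) ** (
            1.0 / HYPSOMETRIC_EXPONENT
        )
        if scenario.noise.baro_std > 0:
            pres = pres + rng.normal(0.0, scenario.noise.baro_std, pres.shape)

        recordings[foot] = IMURecording(
            time=t, acc=acc_out, gyr=gyr_out, baro_time=t_baro, baro=pres,
            frame=frame, foot=foot,
            meta={"subject_id": scenario.subject.subject_id, "lateral": lateral[foot]},
        )
        vel_gf[foot] = v_gf
        pitch[foot] = th
        orientation[foot] = Rotation.from_matrix(R_BASE) * Rotation.from_euler(
            "z", th[:, None]
        )
        events[foot] = _events_for(rows, ics[-1])
        static_w[foot] = _static_windows(rows)
        df = pd.DataFrame(rows)
        df.insert(0, "foot", foot)
        stride_frames.append(df)

    strides = pd.concat(stride_frames, ignore_index=True).sort_values("ic")
    strides = strides.reset_index(drop=True)

    # per-sample overground speed: commanded profile inside the run, 0 outside
    run_start, run_end = ics_l[0], ics_l[-1]
    speed_t = np.array([scenario.speed_at(x) for x in t])
    speed_t[(t < run_start) | (t > run_end)] = 0.0

    t_gnss = np.arange(0.0, t_end, 1.0 / scenario.fs_gnss)
    v_gnss = np.interp(t_gnss, t, speed_t)
    if scenario.noise.gnss_speed_std > 0:
        v_gnss = np.clip(
            v_gnss + rng.normal(0.0, scenario.noise.gnss_speed_std, v_gnss.shape), 0, None
        )
    accuracy = np.full_like(t_gnss, 0.05)
    if scenario.noise.gnss_speed_std > 0:
        accuracy = accuracy + np.abs(rng.normal(0.0, 0.02, t_gnss.shape))
    gnss = GNSSTrack(time=t_gnss, speed=v_gnss, accuracy=accuracy)
    if scenario.noise.gnss_outlier_rate > 0:
        gnss, _ = inject_gnss_outliers(
            gnss, scenario.noise.gnss_outlier_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    truth = GroundTruth(
        time=t, speed=speed_t, vel_gf=vel_gf, pitch=pitch, orientation=orientation,
        events=events, static_windows=static_w, strides=strides,
        subject=scenario.subject,
    )
    return recordings, gnss, truth


def inject_gnss_outliers(
    track: GNSSTrack, rate: float, seed: int = 0
) -> tuple[GNSSTrack, np.ndarray]:
    """Corrupt a Bernoulli(rate) subset of samples so they fail the
    reference filters (speed outside 5-20 km/h or accuracy > 0.15 m/s).

    Returns the corrupted track and the flagged indices.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return track, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    hit = rng.random(track.n_samples) < rate
    idx = np.flatnonzero(hit)
    speed = track.speed.copy()
    acc = track.accuracy.copy()
    mode = rng.integers(0, 3, idx.size)
    speed[idx[mode == 0]] = rng.uniform(0.0, 4.9 / 3.6, (mode == 0).sum())
    speed[idx[mode == 1]] = rng.uniform(20.5 / 3.6, 12.0, (mode == 1).sum())
    acc[idx[mode == 2]] = rng.uniform(0.16, 0.8, (mode == 2).sum())
    return GNSSTrack(track.time, speed, acc), idx


def make_cohort(
    n_subjects: int,
    seed: int = 0,
    duration: float = 60.0,
    offset_std: float = 0.15,
    noise: NoiseSpec | None = None,
    speed_profile: Callable[[float], float] | None = None,
    slope_profile: Callable[[float], float] | float = 0.0,
    flight_error: tuple[float, float] = (0.05, 0.03),
) -> list[SyntheticScenario]:
    """Scenarios for a heterogeneous cohort.

    Each subject gets anthropometrics drawn from plausible population ranges
    and a gait-style ``speed_offset`` ~ N(0, offset_std).  The default speed
    profile sweeps the 1.4-5.4 m/s study range slowly so every speed bin is
    populated.  ``flight_error`` (mean, per-stride STD) keeps the swing
    phase imperfectly observable -- the condition under which foot-speed
    features are informative but biased proxies, as on real feet.
    """
    rng = np.random.default_rng(seed)
    scenarios = []
    for i in range(n_subjects):
        gender = int(rng.random() < 0.5)
        height = rng.normal(1.80 if gender == 0 else 1.65, 0.07)
        weight = rng.normal(76.0 if gender == 0 else 59.0, 8.0)
        age = float(rng.integers(20, 55))
        subject = Subject(
            height=float(height), weight=float(weight), gender=gender, age=age,
            speed_offset=float(rng.normal(0.0, offset_std)),
            subject_id=f"S{i:02d}",
        )
        if speed_profile is None:
            lo = float(rng.uniform(1.6, 2.2))
            hi = float(rng.uniform(4.2, 5.2))
            period = duration

            def profile(tt, lo=lo, hi=hi, period=period):
                # slow triangle sweep across the speed range
                phase = (tt % period) / period
                tri = 2 * phase if phase < 0.5 else 2 * (1 - phase)
                return lo + (hi - lo) * tri

            sp = profile
        else:
            sp = speed_profile
        scenarios.append(
            SyntheticScenario(
                duration=duration,
                speed_profile=sp,
                slope_profile=slope_profile,
                subject=subject,
                noise=noise if noise is not None else NoiseSpec(),
                seed=int(rng.integers(0, 2**31 - 1)),
                flight_error_mean=flight_error[0],
                flight_error_std=flight_error[1],
            )
        )
    return scenarios
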