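"""Session file formats: CSV streams plus JSON sidecars.

A session directory holds, per foot, ``imu_<foot>.csv`` (time, acc_x..z in
m/s^2, gyro_x..z in rad/s) and ``baro_<foot>.csv`` (time, pressure in hPa),
plus ``gnss.csv`` (time, speed in m/s, accuracy in m/s), ``subject.json``
and optionally ``truth.json`` (per-stride ground-truth labels and event
times) and ``mask.csv`` (start, end analysis intervals).  Timestamps are
session-relative seconds; sample indices are 0-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from strideforge.gnss import GNSSTrack
from strideforge.preprocess import IMURecording
from strideforge.simulate import GroundTruth, Subject

__all__ = ["SessionBundle", "write_session", "read_session", "load_mask"]

IMU_COLUMNS = ["time", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
GNSS_COLUMNS = ["time", "speed", "accuracy"]


@dataclass
class SessionBundle:
    """Paths composing one session on disk."""

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    def imu(self, foot: str) -> Path:
        return self.root / f"imu_{foot}.csv"

    def baro(self, foot: str) -> Path:
        return self.root / f"baro_{foot}.csv"

    @property
    def gnss(self) -> Path:
        return self.root / "gnss.csv"

    @property
    def subject(self) -> Path:
        return self.root / "subject.json"

    @property
    def truth(self) -> Path:
        return self.root / "truth.json"

    @property
    def mask(self) -> Path:
        return self.root / "mask.csv"


def write_session(
    out_dir: str | Path,
    recordings: dict[str, IMURecording],
    gnss: GNSSTrack,
    subject: Subject,
    truth: GroundTruth | None = None,
    float_format: str = "%.12g",
) -> SessionBundle:
    """Write a session to a directory of CSVs plus JSON sidecars."""
    bundle = SessionBundle(Path(out_dir))
    bundle.root.mkdir(parents=True, exist_ok=True)
    for foot, rec in recordings.items():
        pd.DataFrame(
            np.column_stack([rec.time, rec.acc, rec.gyr]), columns=IMU_COLUMNS
        ).to_csv(bundle.imu(foot), index=False, float_format=float_format)
        if rec.baro is not None:
            pd.DataFrame({"time": rec.baro_time, "pressure": rec.baro}).to_csv(
                bundle.baro(foot), index=False, float_format=float_format
            )
    pd.DataFrame(
        {"time": gnss.time, "speed": gnss.speed, "accuracy": gnss.accuracy}
    ).to_csv(bundle.gnss, index=False, float_format=float_format)
    bundle.subject.write_text(json.dumps(vars(subject), indent=1))
    if truth is not None:
        payload = {
            "strides": truth.strides.to_dict(orient="list"),
            "events": {
                foot: {k: np.asarray(v).tolist() for k, v in ev.items()}
                for foot, ev in truth.events.items()
            },
        }
        bundle.truth.write_text(json.dumps(payload))
    return bundle


def _read_csv_checked(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: column 'time' is not strictly increasing")
    return df


def read_session(
    bundle: SessionBundle | str | Path, frame: str = "functional"
) -> tuple[dict[str, IMURecording], GNSSTrack, Subject]:
    """Read a session directory back into typed streams.

    Missing columns and non-monotone time raise errors naming the file and
    column.  IMU and GNSS time bases must overlap by at least 30 s.
    """
    if not isinstance(bundle, SessionBundle):
        bundle = SessionBundle(Path(bundle))
    recordings = {}
    for foot in ("left", "right"):
        path = bundle.imu(foot)
        if not path.exists():
            raise FileNotFoundError(path)
        df = _read_csv_checked(path, IMU_COLUMNS)
        baro_time = baro = None
        if bundle.baro(foot).exists():
            bdf = _read_csv_checked(bundle.baro(foot), ["time", "pressure"])
            baro_time, baro = bdf["time"].to_numpy(), bdf["pressure"].to_numpy()
        recordings[foot] = IMURecording(
            time=df["time"].to_numpy(),
            acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
            gyr=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
            baro_time=baro_time, baro=baro, frame=frame, foot=foot,
        )
    gdf = _read_csv_checked(bundle.gnss, GNSS_COLUMNS)
    gnss = GNSSTrack(gdf["time"].to_numpy(), gdf["speed"].to_numpy(),
                     gdf["accuracy"].to_numpy())
    t_imu = recordings["left"].time
    overlap = min(t_imu[-1], gnss.time[-1]) - max(t_imu[0], gnss.time[0])
    if overlap < 30.0:
        raise ValueError(f"IMU and GNSS time bases overlap by only {overlap:.1f} s (< 30 s)")
    subject = Subject(**json.loads(bundle.subject.read_text())) if bundle.subject.exists() else Subject()
    return recordings, gnss, subject


def load_mask(path: str | Path) -> list[tuple[float, float]]:
    """Analysis-interval mask: CSV with ``start``/``end`` seconds columns."""
    df = pd.read_csv(path)
    for col in ("start", "end"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return [(float(r.start), float(r.end)) for r in df.itertuples()]
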