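"""Sensor log I/O and clock synchronization.

A recording session consists of two asynchronous streams per shoe: four
triaxial plantar force sensors sampled at ~400 Hz (heel, first metatarsal
head, fifth metatarsal head, toe) and one toe-mounted IMU at ~70 Hz emitting
calibrated-or-raw specific force plus an orientation quaternion. Both clocks
count seconds from the recording trigger (t = 0). Logs are plain CSV; session
metadata is a small YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, UsageError

SENSOR_NAMES = ("heel", "mt1", "mt5", "toe")

FORCE_COLUMNS = ["time"] + [
    f"{axis}{i}" for i in range(1, 5) for axis in ("fx", "fy", "fz")
]
IMU_COLUMNS = ["time", "ax", "ay", "az", "qw", "qx", "qy", "qz"]


@dataclass(frozen=True)
class SessionMeta:
    """Participant and recording metadata for one session."""

    participant_id: str
    group: str  # "young" | "older"
    height: float  # m
    body_mass: float  # kg
    shoe_side: str = "right"
    force_rate_hz: float = 400.0
    imu_rate_hz: float = 70.0
    imu_initial_height: float = 0.03  # m, IMU mount height above ground

    def __post_init__(self):
        if self.group not in ("young", "older"):
            raise UsageError(f"unknown group {self.group!r}")
        if self.shoe_side not in ("left", "right"):
            raise UsageError(f"unknown shoe side {self.shoe_side!r}")
        if not 0.5 < self.height < 2.5:
            raise UsageError(f"height {self.height} m outside (0.5, 2.5)")
        if not 20.0 < self.body_mass < 200.0:
            raise UsageError(f"body mass {self.body_mass} kg outside (20, 200)")
        if self.force_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise UsageError("sampling rates must be positive")


@dataclass
class ForceStream:
    """Shoe-local triaxial forces of the four plantar sensors on one clock.

    ``forces`` has shape (n_samples, 4, 3): sensor order heel, MT1, MT5, toe;
    axis order (x' foot width, y' foot length, z' sole normal), newtons.
    """

    time: np.ndarray
    forces: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.shape != (self.time.size, 4, 3):
            raise UsageError(
                f"forces shape {self.forces.shape} != ({self.time.size}, 4, 3)"
            )
        _check_time(self.time)
        if np.isnan(self.forces).any():
            raise DataError("force stream contains NaN")

    @property
    def total_vertical(self) -> np.ndarray:
        """Sum of the four local-frame vertical channels, N."""
        return self.forces[:, :, 2].sum(axis=1)

    @property
    def rate_hz(self) -> float:
        return (self.time.size - 1) / (self.time[-1] - self.time[0])


@dataclass
class ImuStream:
    """Toe IMU stream: specific force (m/s^2) and unit orientation quaternion.

    Quaternions are Hamilton convention, scalar first (w, x, y, z), rotating
    IMU-local vectors into the world frame.
    """

    time: np.ndarray
    accel: np.ndarray  # (n, 3)
    quat: np.ndarray  # (n, 4), renormalized on construction

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        _check_time(self.time)
        n = self.time.size
        if self.accel.shape != (n, 3) or self.quat.shape != (n, 4):
            raise UsageError("accel must be (n,3) and quat (n,4)")
        norms = np.linalg.norm(self.quat, axis=1)
        if (norms < 1e-3).any():
            raise DataError("zero-norm quaternion in IMU stream")
        self.quat = self.quat / norms[:, None]

    @property
    def rate_hz(self) -> float:
        return (self.time.size - 1) / (self.time[-1] - self.time[0])


@dataclass
class RawSession:
    """One synchronized recording: metadata plus both sensor streams."""

    meta: SessionMeta
    force: ForceStream
    imu: ImuStream

    def __post_init__(self):
        t0 = max(self.force.time[0], self.imu.time[0])
        t1 = min(self.force.time[-1], self.imu.time[-1])
        spans = [
            self.force.time[-1] - self.force.time[0],
            self.imu.time[-1] - self.imu.time[0],
        ]
        if t1 - t0 < 0.9 * max(spans):
            raise DataError("force and IMU time ranges overlap by less than 90%")


def _check_time(time: np.ndarray) -> None:
    if time.size == 0:
        raise UsageError("empty time base")
    if np.isnan(time).any():
        raise DataError("NaN in time base")
    if not (np.diff(time) > 0).all():
        raise DataError("time base is not strictly increasing")


# ---------------------------------------------------------------------------
# CSV / YAML round-trip


def read_force_log(path: str | Path) -> ForceStream:
    """Read a force CSV (``time,fx1,fy1,fz1,...,fx4,fy4,fz4``, SI units)."""
    df = pd.read_csv(path)
    missing = [c for c in FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"force log {path}: missing columns {missing}")
    forces = df[FORCE_COLUMNS[1:]].to_numpy(dtype=float).reshape(-1, 4, 3)
    return ForceStream(time=df["time"].to_numpy(dtype=float), forces=forces)


def write_force_log(path: str | Path, stream: ForceStream) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.time, stream.forces.reshape(len(stream.time), 12)]),
        columns=FORCE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_imu_log(path: str | Path) -> ImuStream:
    """Read an IMU CSV (``time,ax,ay,az,qw,qx,qy,qz``)."""
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU log {path}: missing columns {missing}")
    return ImuStream(
        time=df["time"].to_numpy(dtype=float),
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        quat=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
    )


def write_imu_log(path: str | Path, stream: ImuStream) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.time, stream.accel, stream.quat]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_session_meta(path: str | Path) -> SessionMeta:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        return SessionMeta(**data)
    except TypeError as exc:
        raise FormatError(f"metadata {path}: {exc}") from exc


def write_session_meta(path: str | Path, meta: SessionMeta) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(meta.__dict__), fh, sort_keys=False)


def read_session(directory: str | Path) -> RawSession:
    """Load a session directory (force.csv, imu.csv, meta.yaml)."""
    directory = Path(directory)
    return RawSession(
        meta=read_session_meta(directory / "meta.yaml"),
        force=read_force_log(directory / "force.csv"),
        imu=read_imu_log(directory / "imu.csv"),
    )


def write_session(directory: str | Path, session: RawSession) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_session_meta(directory / "meta.yaml", session.meta)
    write_force_log(directory / "force.csv", session.force)
    write_imu_log(directory / "imu.csv", session.imu)
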