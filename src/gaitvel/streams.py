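"""Data containers for IMU, orientation and optical-marker streams.

Axis convention (sensor and gravity-aligned global frames alike):
X = antero-posterior, positive forward; Y = medio-lateral, positive to the
right; Z = vertical, aligned with gravity and positive downward.

Streams are read and written as plain delimited text so that recordings can
be inspected and produced with any tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IMUStream",
    "OrientationStream",
    "MarkerTrajectory",
    "AXIS_NAMES",
    "TIME_EPS",
]

#: column order of the three axes everywhere in the package
AXIS_NAMES = ("ap", "ml", "vt")

#: tolerance (s) used when classifying a sample against a stride boundary,
#: absorbing float representation error of accumulated event times; far
#: below any sampling period of interest
TIME_EPS = 1e-9

IMU_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
QUAT_COLUMNS = ["time_s", "qw", "qx", "qy", "qz"]

_UNIFORMITY_TOL = 1e-6  # seconds


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        raise ValueError("stream must contain at least two samples")
    if np.ptp(dt) > _UNIFORMITY_TOL:
        raise ValueError("stream time base must be uniform to within 1e-6 s")
    return float(dt.mean())


@dataclass
class IMUStream:
    """Uniformly sampled tri-axial accelerometer + gyroscope recording.

    ``accel`` is specific force in the sensor frame (m/s^2): a sensor at rest
    with axes aligned to the global frame reads ``(0, 0, -g)`` because the Z
    axis points down.  ``gyro`` is angular velocity (rad/s).
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sampling_rate: float
    site: str = "pelvis"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.time.size
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must have shape (n_samples, 3)")
        if not (
            np.isfinite(self.time).all()
            and np.isfinite(self.accel).all()
            and np.isfinite(self.gyro).all()
        ):
            raise ValueError("stream values must be finite")
        dt = _check_uniform(self.time)
        if abs(dt * self.sampling_rate - 1.0) > 1e-3:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} inconsistent with time step {dt}"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.time, self.accel, self.gyro]), columns=IMU_COLUMNS
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site: str = "pelvis", subject_id: str = "") -> "IMUStream":
        df = pd.read_csv(path)
        missing = [c for c in IMU_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"IMU file {path} missing columns {missing}")
        time = df["time_s"].to_numpy(dtype=float)
        rate = 1.0 / float(np.mean(np.diff(time)))
        return cls(
            time=time,
            accel=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
            gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float),
            sampling_rate=rate,
            site=site,
            subject_id=subject_id,
        )


@dataclass
class OrientationStream:
    """Unit quaternions (scalar-first, sensor frame -> gravity-aligned global
    frame) on the same time base as the IMU stream they accompany."""

    time: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.shape != (self.time.size, 4):
            raise ValueError("quaternions must have shape (n_samples, 4)")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must have unit norm to within 1e-6")

    @classmethod
    def identity(cls, time) -> "OrientationStream":
        time = np.asarray(time, dtype=float)
        q = np.zeros((time.size, 4))
        q[:, 0] = 1.0
        return cls(time=time, quaternions=q)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            np.column_stack([self.time, self.quaternions]), columns=QUAT_COLUMNS
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OrientationStream":
        df = pd.read_csv(path)
        missing = [c for c in QUAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"quaternion file {path} missing columns {missing}")
        return cls(
            time=df["time_s"].to_numpy(dtype=float),
            quaternions=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
        )


@dataclass
class MarkerTrajectory:
    """Optical-marker 3D position trace (m) in the gravity-aligned global
    frame, used as a reference for progression-velocity extraction."""

    time: np.ndarray
    position: np.ndarray
    sampling_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (self.time.size, 3):
            raise ValueError("position must have shape (n_samples, 3)")
        if not np.isfinite(self.position).all():
            raise ValueError("positions must be finite")
        dt = _check_uniform(self.time)
        if self.sampling_rate == 0.0:
            self.sampling_rate = 1.0 / dt
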