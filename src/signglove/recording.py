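"""Core data container for one dataglove gesture recording.

A recording is a fixed 1.5 s window sampled at 100 Hz (150 samples) with 18
channels: five flex-sensor traces, body-frame triaxial acceleration,
earth-frame (NED) linear acceleration, triaxial angular velocity, and the
orientation quaternion stream (w, x, y, z, Hamilton convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: canonical channel blocks, in file-column order
CHANNEL_BLOCKS = {
    "flex": 5,
    "accel_body": 3,
    "accel_earth": 3,
    "gyro": 3,
    "quat": 4,
}

#: default flat column names for CSV serialization (18 columns)
DEFAULT_COLUMNS = (
    ["flex_1", "flex_2", "flex_3", "flex_4", "flex_5"]
    + ["acc_x", "acc_y", "acc_z"]
    + ["ear_x", "ear_y", "ear_z"]
    + ["gyr_x", "gyr_y", "gyr_z"]
    + ["quat_w", "quat_x", "quat_y", "quat_z"]
)

DEFAULT_FS = 100.0
DEFAULT_WINDOW = 150


@dataclass
class GestureRecording:
    """One gesture trial: 18 synchronized channels plus identity metadata.

    Parameters
    ----------
    subject_id : str
        Signer identifier (folds of the leave-one-subject-out protocol).
    gesture_label : str
        Class name, one of the gesture vocabulary.
    kind : {"static", "dynamic"}
        Whether the sign involves hand motion (dynamic) or only a held
        posture (static).
    flex : (n, 5) array
        Flex-sensor channels, arbitrary units (normalized downstream).
    accel_body : (n, 3) array
        Raw accelerometer output in the glove body frame, m s^-2
        (gravity-contaminated).
    accel_earth : (n, 3) array
        Earth-frame (NED) linear acceleration, m s^-2.
    gyro : (n, 3) array
        Angular velocity in the body frame, rad s^-1.
    quat : (n, 4) array
        Unit orientation quaternions (w, x, y, z) mapping body to earth.
    fs : float
        Sampling rate in Hz, 100 by default.
    meta : dict
        Free-form metadata (AC-noise session flag, simulator ground truth).
    """

    subject_id: str
    gesture_label: str
    kind: str
    flex: np.ndarray
    accel_body: np.ndarray
    accel_earth: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray
    fs: float = DEFAULT_FS
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flex = np.asarray(self.flex, dtype=float)
        self.accel_body = np.asarray(self.accel_body, dtype=float)
        self.accel_earth = np.asarray(self.accel_earth, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"kind must be 'static' or 'dynamic', got {self.kind!r}")
        n = self.flex.shape[0]
        expected = {
            "flex": (n, 5),
            "accel_body": (n, 3),
            "accel_earth": (n, 3),
            "gyro": (n, 3),
            "quat": (n, 4),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.flex.shape[0]

    def to_matrix(self) -> np.ndarray:
        """Stack the 18 channels into an (n, 18) matrix in column order."""
        return np.hstack(
            [self.flex, self.accel_body, self.accel_earth, self.gyro, self.quat]
        )

    @classmethod
    def from_matrix(
        cls,
        mat: np.ndarray,
        subject_id: str,
        gesture_label: str,
        kind: str,
        fs: float = DEFAULT_FS,
        meta: dict | None = None,
    ) -> "GestureRecording":
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 18:
            raise ValueError(f"expected an (n, 18) matrix, got {mat.shape}")
        return cls(
            subject_id=subject_id,
            gesture_label=gesture_label,
            kind=kind,
            flex=mat[:, 0:5],
            accel_body=mat[:, 5:8],
            accel_earth=mat[:, 8:11],
            gyro=mat[:, 11:14],
            quat=mat[:, 14:18],
            fs=fs,
            meta=dict(meta or {}),
        )

    def copy_with(self, **kwargs) -> "GestureRecording":
        return replace(self, **kwargs)
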