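"""Quaternion-based IMU preprocessing for dataglove recordings.

The raw accelerometer measures motion plus an orientation-dependent gravity
component, in a body frame set by the glove's power-up pose.  The pipeline is:

1. gravity compensation: subtract the gravity vector predicted from the
   orientation quaternion, leaving body-frame linear acceleration ``la``;
2. axis rotation: rotate ``la`` into the North-East-Down earth frame with the
   quaternion rotation matrix, giving ``LA``;
3. rolling filters: a 10-point rolling median to kill sampling spikes, an
   optional extra moving average for mains-contaminated sessions, and a final
   10-point moving average;
4. min-max normalization to [0, 1], fitted on the training split only.

Quaternions are Hamilton (w, x, y, z); the rotation matrix maps body-frame
vectors to the earth frame.  Gravity points along +z of the earth frame (NED
"down"), so an accelerometer at rest in the identity orientation reads
(0, 0, g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .recording import GestureRecording

G_DEFAULT = 9.81  # m s^-2

__all__ = [
    "G_DEFAULT",
    "NormalizationState",
    "normalize_quaternion",
    "gravity_vector",
    "compensate_gravity",
    "quaternion_to_rotation",
    "rotate_to_earth",
    "rolling_median",
    "moving_average",
    "clean_recording",
    "fit_normalizer",
    "apply_normalizer",
]


def normalize_quaternion(q: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Return unit quaternions, warning if input norm deviates beyond `tol`.

    Accepts a single (4,) quaternion or an (n, 4) stream.  A zero quaternion
    is an error: it encodes no orientation.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero quaternion has no orientation")
    if np.any(np.abs(norm - 1.0) > tol):
        warnings.warn(
            "non-unit quaternion(s) normalized before use", stacklevel=2
        )
    return q / norm


def gravity_vector(q: np.ndarray, g_mag: float = G_DEFAULT) -> np.ndarray:
    """Gravity in the body frame predicted from orientation.

    For a unit quaternion (w, x, y, z) the body-frame gravity direction is the
    earth "down" axis expressed in body coordinates,

        g = g_mag * (2(qx qz - qw qy), 2(qw qx + qy qz), qw^2 - qx^2 - qy^2 + qz^2),

    which is the third row of the body-to-earth rotation matrix scaled by
    ``g_mag``.  Accepts a (4,) quaternion or (n, 4) stream; returns (3,) or
    (n, 3).
    """
    if g_mag <= 0:
        raise ValueError("g_mag must be positive")
    q = normalize_quaternion(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    g = np.stack(
        [
            2.0 * (x * z - w * y),
            2.0 * (w * x + y * z),
            w * w - x * x - y * y + z * z,
        ],
        axis=-1,
    )
    return g_mag * g


def compensate_gravity(
    a: np.ndarray, q: np.ndarray, g_mag: float = G_DEFAULT
) -> np.ndarray:
    """Subtract per-sample gravity from raw body-frame acceleration.

    ``la[n] = a[n] - gravity_vector(q[n])`` — the body-frame linear
    (motion-only) acceleration.
    """
    a = np.asarray(a, dtype=float)
    q = np.asarray(q, dtype=float)
    if a.shape[0] != q.shape[0]:
        raise ValueError(
            f"acceleration ({a.shape[0]}) and quaternion ({q.shape[0]}) "
            "streams differ in length"
        )
    return a - gravity_vector(q, g_mag)


def quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    """Body-to-earth rotation matrix of a unit quaternion.

    Standard Hamilton-convention matrix; orthonormal with det +1.  Accepts a
    (4,) quaternion or an (n, 4) stream, returning (3, 3) or (n, 3, 3).
    """
    q = normalize_quaternion(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    r = np.empty(q.shape[:-1] + (3, 3))
    r[..., 0, 0] = 1 - 2 * (y * y + z * z)
    r[..., 0, 1] = 2 * (x * y - w * z)
    r[..., 0, 2] = 2 * (x * z + w * y)
    r[..., 1, 0] = 2 * (x * y + w * z)
    r[..., 1, 1] = 1 - 2 * (x * x + z * z)
    r[..., 1, 2] = 2 * (y * z - w * x)
    r[..., 2, 0] = 2 * (x * z - w * y)
    r[..., 2, 1] = 2 * (y * z + w * x)
    r[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return r


def rotate_to_earth(la: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotate body-frame linear acceleration into the NED earth frame.

    ``LA[n] = R(q[n]) @ la[n]``.
    """
    la = np.asarray(la, dtype=float)
    q = np.asarray(q, dtype=float)
    if la.shape[0] != q.shape[0]:
        raise ValueError(
            f"acceleration ({la.shape[0]}) and quaternion ({q.shape[0]}) "
            "streams differ in length"
        )
    r = quaternion_to_rotation(q)
    return np.einsum("nij,nj->ni", r, la)


def _check_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty series")
    return x

def rolling_median(x: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered rolling median; edges filled with the nearest valid value.

    Length-preserving.  Works on a 1-D series or columnwise on an (n, c)
    array.  ``window=1`` is the identity.
    """
    x = _check_series(x)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.shape[0]:
        raise ValueError("window longer than series")
    size = (window, 1) if x.ndim == 2 else window
    return median_filter(x, size=size, mode="nearest")


def moving_average(x: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered moving average; edges filled with the nearest valid value.

    Length-preserving; ``window=1`` is the identity.  1-D or columnwise.
    """
    x = _check_series(x)
    if window < 1:
        raise ValueError("window must be >= 1")
    return uniform_filter1d(x, size=window, axis=0, mode="nearest")


#: channel attributes treated as IMU signals by the spike-removal stage
_IMU_CHANNELS = ("accel_body", "accel_earth", "gyro")
_ALL_SIGNAL_CHANNELS = ("flex", "accel_body", "accel_earth", "gyro")


def clean_recording(
    rec: GestureRecording,
    ac_noise: bool = False,
    median_window: int = 10,
    average_window: int = 10,
    ac_window: int = 10,
) -> GestureRecording:
    """Filter chain applied to one recording.

    In order: rolling median (spike removal) on IMU channels; if the session
    is flagged as mains-contaminated, an extra moving average on all signal
    channels; a final moving average on all signal channels.  Quaternions are
    left untouched (filtering components would break unit norm).
    """
    out = {}
    for name in _ALL_SIGNAL_CHANNELS:
        sig = getattr(rec, name)
        if name in _IMU_CHANNELS:
            sig = rolling_median(sig, median_window)
        if ac_noise:
            sig = moving_average(sig, ac_window)
        sig = moving_average(sig, average_window)
        out[name] = sig
    return rec.copy_with(**out)


@dataclass
class NormalizationState:
    """Per-channel min/max learned from a training split (min-max scaling)."""

    x_min: np.ndarray  # (18,)
    x_max: np.ndarray  # (18,)

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max < x_min for some channel")


def fit_normalizer(recordings) -> NormalizationState:
    """Learn per-channel min/max over a collection of recordings.

    Fit on the training split only: under leave-one-subject-out evaluation
    the held-out signer must not leak into the scaling.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("cannot fit a normalizer on an empty training set")
    mats = np.concatenate([r.to_matrix() for r in recordings], axis=0)
    return NormalizationState(x_min=mats.min(axis=0), x_max=mats.max(axis=0))


def apply_normalizer(
    state: NormalizationState, rec: GestureRecording
) -> GestureRecording:
    """Min-max scale all 18 channels with the fitted state.

    Values from the fitted split land in [0, 1]; unseen values outside the
    fitted range map outside [0, 1] (no clipping).  A constant channel
    (x_max = x_min) maps to 0 with a warning.
    """
    mat = rec.to_matrix()
    span = state.x_max - state.x_min
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn(
            "constant channel(s) in normalizer fit; mapping them to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    scaled = (mat - state.x_min) / safe
    scaled[:, degenerate] = 0.0
    return GestureRecording.from_matrix(
        scaled,
        subject_id=rec.subject_id,
        gesture_label=rec.gesture_label,
        kind=rec.kind,
        fs=rec.fs,
        meta={**rec.meta, "normalized": True},
    )
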