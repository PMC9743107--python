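"""Forward model of a flex+IMU dataglove for testing without the real dataset.

Each synthetic trial inverts the preprocessing chain: a class-specific 3-D
hand path (for dynamic signs) is differentiated twice to earth-frame linear
acceleration; a slowly drifting orientation stream maps it into the body
frame and adds gravity, yielding the raw accelerometer channel; the gyroscope
channel is the angular velocity that generated the quaternion stream; flex
channels follow a smooth logistic transition to a class-specific posture.
Signer variability enters through per-subject hand scale (spatial size),
speed factor (a monotone time warp), flex offsets/gains, and sensor noise.

The noiseless ground truth (earth-frame linear acceleration, velocity and
displacement) rides along in ``rec.meta["truth"]`` so round-trip tests can
compare recovered against commanded motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .imu_preprocess import G_DEFAULT, quaternion_to_rotation
from .recording import DEFAULT_FS, GestureRecording

__all__ = [
    "GestureTemplate",
    "SubjectProfile",
    "forward_model",
    "make_dataset",
    "inject_ac_noise",
    "dynamic_templates",
    "static_templates",
]

FLEX_REST = 0.1  # relaxed-hand flex level, a.u.


def _smootherstep(u: np.ndarray) -> np.ndarray:
    """Quintic ease with zero first and second derivative at both ends, so
    commanded paths start and finish at rest (zero velocity/acceleration)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (u * (6.0 * u - 15.0) + 10.0)


@dataclass
class GestureTemplate:
    """A gesture class: a parametric 3-D curve plus a target flex posture.

    ``path(s)`` maps arc parameter s in [0, 1] to displacement in metres;
    static templates command zero motion.
    """

    name: str
    kind: str  # "static" | "dynamic"
    path: Callable[[np.ndarray], np.ndarray] | None
    flex_posture: np.ndarray  # (5,) in [0, 1]
    duration: float = 1.5

    def __post_init__(self) -> None:
        self.flex_posture = np.asarray(self.flex_posture, dtype=float)
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "dynamic" and self.path is None:
            raise ValueError("dynamic template needs a path")


@dataclass
class SubjectProfile:
    """Per-signer rendering parameters."""

    hand_scale: float = 1.0  # multiplies displacement (hand/arm size)
    speed_factor: float = 1.0  # time-warp exponent (1 = nominal pace)
    flex_offset: np.ndarray = field(default_factory=lambda: np.zeros(5))
    flex_gain: np.ndarray = field(default_factory=lambda: np.ones(5))
    noise_accel: float = 0.05  # m s^-2
    noise_gyro: float = 0.01  # rad s^-1
    noise_flex: float = 0.01  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hand_scale <= 0 or self.speed_factor <= 0:
            raise ValueError("hand_scale and speed_factor must be positive")
        self.flex_offset = np.asarray(self.flex_offset, dtype=float)
        self.flex_gain = np.asarray(self.flex_gain, dtype=float)


# -- built-in template vocabulary ------------------------------------------

def _circle(s):
    th = 2.0 * np.pi * s
    return 0.15 * np.stack([np.cos(th) - 1.0, np.sin(th), np.zeros_like(th)], axis=-1)


def _line(s):
    return np.stack([0.4 * s, np.zeros_like(s), np.zeros_like(s)], axis=-1)


def _zigzag(s):
    # three diagonal strokes in the XZ plane
    y = np.zeros_like(s)
    x = 0.3 * s
    z = 0.1 * np.abs(((3.0 * s) % 2.0) - 1.0) - 0.05
    return np.stack([x, y, z], axis=-1)


def _arc(s):
    th = np.pi * s
    return 0.2 * np.stack([np.zeros_like(th), np.sin(th), 1.0 - np.cos(th)], axis=-1)


def dynamic_templates() -> list[GestureTemplate]:
    """Four well-separated dynamic gestures (distinct curves and postures)."""
    return [
        GestureTemplate("circle", "dynamic", _circle, [0.1, 0.9, 0.9, 0.9, 0.9]),
        GestureTemplate("sweep", "dynamic", _line, [0.9, 0.1, 0.1, 0.9, 0.9]),
        GestureTemplate("zigzag", "dynamic", _zigzag, [0.2, 0.1, 0.9, 0.1, 0.9]),
        GestureTemplate("arc", "dynamic", _arc, [0.8, 0.8, 0.1, 0.1, 0.1]),
    ]


def static_templates() -> list[GestureTemplate]:
    """Four held postures with distinct finger-flexion patterns."""
    return [
        GestureTemplate("fist", "static", None, [0.9, 0.9, 0.9, 0.9, 0.9]),
        GestureTemplate("palm", "static", None, [0.1, 0.1, 0.1, 0.1, 0.1]),
        GestureTemplate("point", "static", None, [0.9, 0.1, 0.9, 0.9, 0.9]),
        GestureTemplate("peace", "static", None, [0.9, 0.1, 0.1, 0.9, 0.9]),
    ]


# -- quaternion kinematics --------------------------------------------------

def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_exp(v: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (body frame) -> unit quaternion."""
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / theta
    half = theta / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _orientation_stream(
    n: int, dt: float, rng: np.random.Generator, tilt_sigma: float = 0.05,
    max_tilt_deg: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Slow random-walk tilt around the identity pose.

    Returns quaternions (n, 4) and the body-frame angular velocity (n, 3)
    that generated them, so the gyro channel is consistent with the
    quaternion stream by construction.
    """
    # smooth band-limited angular velocity
    raw = rng.normal(0.0, tilt_sigma, size=(n, 3))
    kernel = np.ones(15) / 15.0
    omega = np.apply_along_axis(
        lambda s: np.convolve(s, kernel, mode="same"), 0, raw
    )
    quats = np.empty((n, 4))
    q = np.array([1.0, 0.0, 0.0, 0.0])
    max_tilt = np.deg2rad(max_tilt_deg)
    for i in range(n):
        quats[i] = q
        dq = _quat_exp(omega[i] * dt)
        q_next = _quat_multiply(q, dq)
        q_next /= np.linalg.norm(q_next)
        # cap total tilt: if the step would leave the cone, hold the pose
        if 2.0 * np.arccos(np.clip(abs(q_next[0]), -1.0, 1.0)) > max_tilt:
            q_next = q
            omega[i] = 0.0
        q = q_next
    return quats, omega


def forward_model(
    template: GestureTemplate,
    profile: SubjectProfile,
    fs: float = DEFAULT_FS,
    duration: float = 1.5,
    subject_id: str = "s01",
    trial: int = 0,
) -> GestureRecording:
    """Render one 150-sample, 18-channel recording from a template.

    Body-frame acceleration is R^T LA + gravity(q) plus sensor noise, so
    running the gravity-compensation + axis-rotation pipeline on a noiseless
    recording recovers the stored ground-truth earth-frame acceleration.
    """
    rng = np.random.default_rng(profile.seed)
    n = int(round(fs * duration))
    dt = 1.0 / fs
    t = np.arange(n) * dt
    u = t / duration

    if template.kind == "dynamic":
        warped = u ** profile.speed_factor
        x = profile.hand_scale * template.path(_smootherstep(warped))
    else:
        x = np.zeros((n, 3))
    v = np.gradient(x, dt, axis=0)
    la_earth = np.gradient(v, dt, axis=0)

    quats, omega = _orientation_stream(n, dt, rng)
    rot = quaternion_to_rotation(quats)  # body -> earth
    la_body = np.einsum("nji,nj->ni", rot, la_earth)  # R^T LA
    g_body = G_DEFAULT * rot[:, 2, :]  # third row = earth-down in body frame
    accel_body = la_body + g_body + rng.normal(0.0, profile.noise_accel, (n, 3))
    # the earth-axis channel is computed from the (noisy) body channel the
    # same way the glove firmware does
    accel_earth = np.einsum(
        "nij,nj->ni", rot, accel_body - g_body
    )
    gyro = omega + rng.normal(0.0, profile.noise_gyro, (n, 3))

    # logistic transition from rest to the commanded posture
    t0, tau = 0.3 * duration, 0.08 * duration
    ramp = 1.0 / (1.0 + np.exp(-(t - t0) / tau))
    flex = FLEX_REST + np.outer(ramp, template.flex_posture - FLEX_REST)
    flex = flex * profile.flex_gain + profile.flex_offset
    flex = flex + rng.normal(0.0, profile.noise_flex, (n, 5))

    return GestureRecording(
        subject_id=subject_id,
        gesture_label=template.name,
        kind=template.kind,
        flex=flex,
        accel_body=accel_body,
        accel_earth=accel_earth,
        gyro=gyro,
        quat=quats,
        fs=fs,
        meta={
            "trial": trial,
            "truth": {
                "accel_earth": la_earth,
                "velocity": v,
                "displacement": x,
            },
        },
    )


def make_dataset(
    n_subjects: int,
    templates: list[GestureTemplate],
    seed: int = 0,
    n_trials: int = 10,
    fs: float = DEFAULT_FS,
    duration: float = 1.5,
    noise_accel: float = 0.05,
    noise_gyro: float = 0.01,
    noise_flex: float = 0.01,
) -> list[GestureRecording]:
    """Class-balanced cohort: ``n_trials`` repetitions per subject per gesture.

    Subject profiles are drawn once per signer (hand scale U(0.8, 1.2), speed
    factor U(0.7, 1.4), small flex offset/gain perturbations); each trial
    additionally jitters pace and size slightly.  Bit-deterministic for a
    given seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-subject-out)")
    rng = np.random.default_rng(seed)
    recordings = []
    for s in range(n_subjects):
        subject_id = f"s{s + 1:02d}"
        hand_scale = rng.uniform(0.8, 1.2)
        speed = rng.uniform(0.7, 1.4)
        flex_offset = rng.normal(0.0, 0.02, 5)
        flex_gain = rng.uniform(0.9, 1.1, 5)
        for template in templates:
            for trial in range(n_trials):
                profile = SubjectProfile(
                    hand_scale=hand_scale * rng.uniform(0.95, 1.05),
                    speed_factor=speed * rng.uniform(0.9, 1.1),
                    flex_offset=flex_offset,
                    flex_gain=flex_gain,
                    noise_accel=noise_accel,
                    noise_gyro=noise_gyro,
                    noise_flex=noise_flex,
                    seed=int(rng.integers(2**31 - 1)),
                )
                recordings.append(
                    forward_model(
                        template,
                        profile,
                        fs=fs,
                        duration=duration,
                        subject_id=subject_id,
                        trial=trial,
                    )
                )
    return recordings


def inject_ac_noise(
    rec: GestureRecording,
    freq: float = 50.0,
    amplitude: float = 0.1,
    phase: float = 0.0,
) -> GestureRecording:
    """Add mains interference: a sinusoid on every signal channel.

    ``amplitude * cos(2 pi f t + phase)`` is added to the flex, body/earth
    acceleration and gyro channels (the quaternion stream is digital and
    stays clean); the recording is flagged ``ac_noise`` in metadata.  A
    cosine is used so that at ``freq`` equal to the Nyquist frequency the
    sampled interference is the alternating sequence rather than identically
    zero.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    s = amplitude * np.cos(2.0 * np.pi * freq * t + phase)
    return rec.copy_with(
        flex=rec.flex + s[:, None],
        accel_body=rec.accel_body + s[:, None],
        accel_earth=rec.accel_earth + s[:, None],
        gyro=rec.gyro + s[:, None],
        meta={**rec.meta, "ac_noise": True},
    )
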