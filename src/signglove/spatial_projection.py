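"""Spatial projection images for dynamic gestures.

A dynamic sign is defined by the spatial pattern the hand traces, not by how
fast the signer moves or how large their hand is.  Earth-frame linear
acceleration is double-integrated to a 3-D displacement path, projected onto
the XY, YZ and ZX planes, min-max normalized per axis (removing hand-size
scale), and rasterized into three fixed-size grayscale images.  Because the
path is drawn as a set of points, its traversal speed drops out: any monotone
time-reparameterization of a noiseless trajectory yields the same image.

Static signs have no meaningful trajectory and are rejected by
:func:`make_projection_images`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from scipy.integrate import cumulative_trapezoid

from .recording import GestureRecording

IMAGE_SIZE = 224
STROKE_WIDTH = 7
SUPERSAMPLE = 2  # render at 448, area-resample down
MARGIN = 0.05  # padding around the unit square

PLANES = ("XY", "YZ", "ZX")
#: displacement component indices (horizontal, vertical) per plane
_PLANE_AXES = {"XY": (0, 1), "YZ": (1, 2), "ZX": (2, 0)}

__all__ = [
    "IMAGE_SIZE",
    "STROKE_WIDTH",
    "PLANES",
    "Trajectory3D",
    "PlanePath",
    "ProjectionImageSet",
    "integrate_acceleration",
    "project_to_planes",
    "normalize_path",
    "rasterize_path",
    "make_projection_images",
]


@dataclass
class Trajectory3D:
    """Velocity and displacement recovered from acceleration.

    Both start at zero: the recording protocol has the hand at rest when the
    window opens, so zero initial conditions are the physical ones.
    """

    v: np.ndarray  # (n, 3) m/s
    x: np.ndarray  # (n, 3) m


@dataclass
class PlanePath:
    """Ordered 2-D projection of the displacement path onto one plane."""

    plane: str  # "XY" | "YZ" | "ZX"
    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class ProjectionImageSet:
    """Three fixed-size grayscale rasters, one per projection plane.

    Pixel values lie in [0, 1] with ink = 1 on a 0 background, so images are
    sparse-positive.
    """

    images: dict[str, np.ndarray]  # plane -> (224, 224) float array

    def __post_init__(self) -> None:
        if set(self.images) != set(PLANES):
            raise ValueError(f"expected planes {PLANES}, got {set(self.images)}")
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"images differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or shape[0] != shape[1]:
            raise ValueError(f"images must be square, got {shape}")

    def as_array(self) -> np.ndarray:
        """Stack in canonical plane order -> (3, 224, 224)."""
        return np.stack([self.images[p] for p in PLANES])


def integrate_acceleration(a: np.ndarray, fs: float) -> Trajectory3D:
    """Cumulative trapezoidal double integration, zero initial conditions."""
    a = np.asarray(a, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples to integrate")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite acceleration")
    dt = 1.0 / fs
    v = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    x = cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)
    return Trajectory3D(v=v, x=x)


def project_to_planes(traj: Trajectory3D) -> list[PlanePath]:
    """Drop one coordinate at a time: XY=(x,y), YZ=(y,z), ZX=(z,x)."""
    paths = []
    for plane in PLANES:
        i, j = _PLANE_AXES[plane]
        paths.append(PlanePath(plane=plane, points=traj.x[:, (i, j)]))
    return paths


def normalize_path(
    p: PlanePath,
    joint: bool = False,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-12,
) -> PlanePath:
    """Min-max scale each axis of the path to [0, 1].

    Hand size is a near-uniform scale on displacement, so normalization makes
    paths signer-size independent.  With ``joint=True`` both axes share one
    min/max pair (preserving aspect ratio) instead of the default independent
    per-axis scaling.

    A degenerate axis is centered at 0.5.  Degeneracy is judged with a small
    tolerance relative to the larger axis span (plus an absolute floor in
    metres): an out-of-plane coordinate that is zero up to float rounding
    must not be min-max amplified into a spurious full-scale pattern.
    """
    pts = p.points
    if pts.shape[0] == 0:
        raise ValueError("empty path")
    if joint:
        lo = np.full(2, pts.min())
        hi = np.full(2, pts.max())
    else:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
    span = hi - lo
    threshold = abs_tol + rel_tol * span.max()
    out = np.empty_like(pts)
    for axis in range(2):
        if span[axis] <= threshold:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (pts[:, axis] - lo[axis]) / span[axis]
    return PlanePath(plane=p.plane, points=out)


def rasterize_path(
    p: PlanePath,
    size: int = IMAGE_SIZE,
    stroke: int = STROKE_WIDTH,
    supersample: int = SUPERSAMPLE,
    margin: float = MARGIN,
) -> np.ndarray:
    """Draw the normalized path as a polyline and raster to a size x size image.

    Rendered at ``supersample * size`` with round joins/caps, then
    area-resampled down (giving smooth anti-aliased edges).  Output is float
    in [0, 1] with ink = 1.  Deterministic: identical paths give bit-identical
    rasters.
    """
    pts = np.asarray(p.points, dtype=float)
    big = size * supersample
    canvas = Image.new("L", (big, big), 0)
    if pts.shape[0] == 0:
        warnings.warn("empty path; returning blank raster", stacklevel=2)
        small = canvas.resize((size, size), Image.BOX)
        return np.asarray(small, dtype=float) / 255.0

    # map unit square -> pixel coordinates with margin; flip y so that larger
    # path-y is higher in the image (plot convention)
    scale = big * (1.0 - 2.0 * margin)
    off = big * margin
    px = off + pts[:, 0] * scale
    py = big - 1 - (off + pts[:, 1] * scale)
    xy = list(zip(px.tolist(), py.tolist()))

    draw = ImageDraw.Draw(canvas)
    w = stroke * supersample
    if len(xy) == 1:
        x0, y0 = xy[0]
        r = w / 2.0
        draw.ellipse([x0 - r, y0 - r, x0 + r, y0 + r], fill=255)
    else:
        draw.line(xy, fill=255, width=w, joint="curve")
        # PIL's wide line has square caps; round them explicitly
        for x0, y0 in (xy[0], xy[-1]):
            r = w / 2.0
            draw.ellipse([x0 - r, y0 - r, x0 + r, y0 + r], fill=255)
    small = canvas.resize((size, size), Image.BOX)
    return np.asarray(small, dtype=float) / 255.0


def make_projection_images(
    rec: GestureRecording,
    size: int = IMAGE_SIZE,
    stroke: int = STROKE_WIDTH,
    joint_axes: bool = False,
) -> ProjectionImageSet:
    """Full chain for one dynamic recording: integrate, project, normalize,
    rasterize all three planes.

    Raises for static recordings: a held posture produces no meaningful
    trajectory, so the projection step is defined only for dynamic signs.
    """
    if rec.kind != "dynamic":
        raise ValueError(
            "spatial projection images are defined for dynamic gestures only; "
            f"got a {rec.kind!r} recording"
        )
    traj = integrate_acceleration(rec.accel_earth, rec.fs)
    images = {}
    for path in project_to_planes(traj):
        norm = normalize_path(path, joint=joint_axes)
        images[path.plane] = rasterize_path(norm, size=size, stroke=stroke)
    return ProjectionImageSet(images=images)
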