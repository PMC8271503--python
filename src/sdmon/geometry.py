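"""Planar homography calibration and ground-plane <-> image mapping.

A fixed monocular camera observes pedestrians on a planar ground (z = 0).
The world ground plane (meters) and the image plane (pixels) are related by
a 3x3 projective transformation M, stored here in the world->image
direction.  Detected pedestrian foot points are mapped into bird's-eye-view
world coordinates through M^-1, after which all distances are metric.

Coordinate conventions
----------------------
Image points are (u, v) with u the pixel column (increasing rightward) and
v the pixel row (increasing *downward*), origin at the top-left corner, so
the bottom edge of a bounding box has the larger v.  World points are
(x, y) in meters on the ground plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "UnmappablePointError",
    "Homography",
    "estimate_homography",
    "world_to_image",
    "image_to_world",
    "read_homography",
    "write_homography",
]

#: Determinant magnitude below which a 3x3 matrix is treated as singular.
_SINGULAR_TOL = 1e-12


class CalibrationError(ValueError):
    """Homography estimation failed (too few or degenerate correspondences)."""


class UnmappablePointError(ValueError):
    """A point maps to the horizon line (vanishing homogeneous scale)."""


def _normalize_matrix(m: np.ndarray) -> np.ndarray:
    """Scale a projective matrix to the canonical representative.

    m33 is forced to 1 when it carries non-negligible weight; otherwise the
    matrix is scaled to unit Frobenius norm with its largest-magnitude entry
    made positive, so equal maps compare equal regardless of the arbitrary
    projective scale (including its sign).
    """
    m = np.asarray(m, dtype=float)
    fro = np.linalg.norm(m)
    if fro == 0.0:
        raise CalibrationError("zero homography matrix")
    if abs(m[2, 2]) > 1e-9 * fro:
        return m / m[2, 2]
    m = m / fro
    i, j = np.unravel_index(np.argmax(np.abs(m)), m.shape)
    return m if m[i, j] > 0 else -m


@dataclass(frozen=True)
class Homography:
    """World->image projective map on the ground plane.

    Parameters
    ----------
    m : (3, 3) array_like
        Projective matrix mapping homogeneous world coordinates
        ``[x, y, 1]`` (meters) to homogeneous image coordinates (pixels).
        Stored normalized (``m[2, 2] == 1`` whenever possible).
    """

    m: np.ndarray = field()

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography entries must be finite")
        m = _normalize_matrix(m)
        if abs(np.linalg.det(m)) <= _SINGULAR_TOL:
            raise CalibrationError("homography matrix is singular")
        m.setflags(write=False)
        object.__setattr__(self, "m", m)

    @property
    def inverse(self) -> np.ndarray:
        """Image->world matrix M^-1 (not re-normalized)."""
        return np.linalg.inv(self.m)


def _apply(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 projective matrix to (..., 2) points, dehomogenizing."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2:
        raise ValueError("points must have 2 coordinates")
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = hom @ matrix.T
    w = out[:, 2]
    scale = max(np.linalg.norm(matrix), 1.0)
    if np.any(np.abs(w) < 1e-12 * scale):
        raise UnmappablePointError(
            "point lies on the horizon of the projective map "
            "(homogeneous scale ~ 0)"
        )
    mapped = out[:, :2] / w[:, None]
    return mapped[0] if single else mapped


def world_to_image(h: Homography, points) -> np.ndarray:
    """Project ground-plane world points (meters) to pixel coordinates.

    Parameters
    ----------
    h : Homography
    points : (2,) or (n, 2) array_like
        World points ``(x, y)`` in meters.

    Returns
    -------
    ndarray of the same leading shape with pixel coordinates ``(u, v)``.

    Raises
    ------
    UnmappablePointError
        If a point projects to the horizon (zero homogeneous scale).
    """
    return _apply(h.m, points)


def image_to_world(h: Homography, points) -> np.ndarray:
    """Back-project pixel coordinates to bird's-eye-view world meters.

    Inverse perspective mapping: dehomogenized ``M^-1 [u, v, 1]^T``,
    assuming the point lies on the ground plane z = 0.
    """
    return _apply(h.inverse, points)


def _hartley_normalization(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform taking points to centroid 0, mean radius sqrt(2)."""
    centroid = points.mean(axis=0)
    dists = np.linalg.norm(points - centroid, axis=1)
    mean_dist = dists.mean()
    if mean_dist < 1e-12:
        raise CalibrationError("correspondence points are all coincident")
    s = np.sqrt(2.0) / mean_dist
    t = np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )
    normalized = (points - centroid) * s
    return t, normalized


def estimate_homography(world_points, image_points) -> Homography:
    """Estimate the world->image homography by the normalized DLT.

    Operator-selected key points with known ground-plane positions and their
    pixel locations determine M; four correspondences in general position
    suffice, more are solved in the algebraic least-squares sense.  Both
    point sets are Hartley-normalized before building the 2n x 9 direct
    linear transform system, whose least-squares null vector (smallest
    right singular vector) gives the matrix.  For noise-free
    correspondences generated by a projective map, the generating map is
    recovered up to scale.

    Parameters
    ----------
    world_points, image_points : (n, 2) array_like, n >= 4
        Matched ground-plane (meters) and pixel coordinates.

    Returns
    -------
    Homography

    Raises
    ------
    CalibrationError
        Fewer than 4 correspondences, or a degenerate configuration
        (coincident/collinear points yielding a singular system).
    """
    world = np.asarray(world_points, dtype=float)
    image = np.asarray(image_points, dtype=float)
    if world.ndim != 2 or world.shape[1] != 2 or image.shape != world.shape:
        raise CalibrationError(
            "world and image points must be matched (n, 2) arrays"
        )
    n = len(world)
    if n < 4:
        raise CalibrationError(f"need at least 4 correspondences, got {n}")
    if not (np.all(np.isfinite(world)) and np.all(np.isfinite(image))):
        raise CalibrationError("correspondence coordinates must be finite")

    t_world, wn = _hartley_normalization(world)
    t_image, im = _hartley_normalization(image)

    a = np.zeros((2 * n, 9))
    for i, ((x, y), (u, v)) in enumerate(zip(wn, im)):
        a[2 * i] = [-x, -y, -1.0, 0.0, 0.0, 0.0, u * x, u * y, u]
        a[2 * i + 1] = [0.0, 0.0, 0.0, -x, -y, -1.0, v * x, v * y, v]

    _, svals, vt = np.linalg.svd(a)
    # rank < 8 means the correspondences do not pin down a unique map
    if svals[7] < 1e-9 * svals[0]:
        raise CalibrationError(
            "degenerate correspondence configuration (collinear or "
            "coincident points): homography is not uniquely determined"
        )
    h_norm = vt[-1].reshape(3, 3)
    m = np.linalg.inv(t_image) @ h_norm @ t_world
    try:
        return Homography(m)
    except CalibrationError as exc:  # singular recovered matrix
        raise CalibrationError(f"calibration produced a singular map: {exc}")


def read_homography(path) -> Homography:
    """Load a homography from the JSON interchange file.

    The file is ``{"M": [[...]x3], "direction": "world_to_image" |
    "image_to_world", "units": "m,px"}``.  A matrix stored in the
    image->world direction is inverted on load so the in-memory object is
    always world->image.
    """
    with open(path) as fh:
        payload = json.load(fh)
    m = np.asarray(payload["M"], dtype=float)
    direction = payload.get("direction", "world_to_image")
    if direction == "image_to_world":
        m = np.linalg.inv(m)
    elif direction != "world_to_image":
        raise ValueError(f"unknown homography direction {direction!r}")
    return Homography(m)


def write_homography(path, h: Homography) -> None:
    """Write a homography to the JSON interchange file (world->image)."""
    payload = {
        "M": np.asarray(h.m).tolist(),
        "direction": "world_to_image",
        "units": "m,px",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
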