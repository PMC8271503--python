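"""Per-frame social-distancing statistics in ground-plane world coordinates.

Given pedestrian positions inside a region of interest (ROI) of area A0, a
frame is summarized by the pedestrian count n, the social density
rho = n / A0 (1/m^2), the list of pairwise Euclidean distances, the number
of distancing violations v (pairs closer than the minimum distance d_c),
the violation ratio r_v = v / n, and d_avg, the mean over pedestrians of
each pedestrian's distance to their nearest neighbour.

Two printed conventions are preserved as options: the violation double sum
over ordered pairs counts every violating pair twice (``pair_counting=
"ordered"``), while the default counts unordered pairs once; the violation
indicator is strict (d < d_c) by default with an inclusive variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Polygon

from .detection import (
    DEFAULT_PEDESTRIAN_LABEL,
    DEFAULT_SCORE_THRESHOLD,
    Frame,
    filter_pedestrians,
    pixel_pose,
)
from .geometry import Homography, UnmappablePointError, image_to_world

__all__ = [
    "SceneConfig",
    "FrameStats",
    "polygon_area",
    "roi_filter",
    "pairwise_distances",
    "count_violations",
    "social_density",
    "analyze_frame",
    "stats_from_world_points",
]

logger = logging.getLogger(__name__)

#: Default confidence-interval mass behind the violation-probability budget
#: U0 = 1 - PCI^2 with PCI = 0.95.
DEFAULT_U0 = 1.0 - 0.95**2


def _as_polygon(polygon) -> Polygon:
    poly = Polygon(np.asarray(polygon, dtype=float))
    if len(poly.exterior.coords) - 1 < 3:
        raise ValueError("ROI polygon needs at least 3 vertices")
    if not poly.is_valid:
        raise ValueError("ROI polygon must be simple (non-self-intersecting)")
    if poly.area <= 0.0:
        raise ValueError("ROI polygon is degenerate (zero area)")
    return poly


def polygon_area(polygon) -> float:
    """Ground-plane area (m^2) of a simple polygon given as (n, 2) vertices."""
    return float(_as_polygon(polygon).area)


def roi_filter(points, polygon) -> np.ndarray:
    """Subset of world points inside or on the boundary of the ROI polygon.

    Boundary-inclusive: a pedestrian standing exactly on the ROI border is
    counted, which prevents flicker in/out on edge positions.  Input order
    is preserved.
    """
    poly = _as_polygon(polygon)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.empty((0, 2))
    mask = shapely.covers(poly, shapely.points(pts))
    return pts[mask]


def _roi_mask(points: np.ndarray, poly: Polygon) -> np.ndarray:
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    return shapely.covers(poly, shapely.points(points))


@dataclass
class SceneConfig:
    """Scene description: ROI geometry and distancing conventions.

    Parameters
    ----------
    roi_polygon : (n, 2) array_like
        Simple polygon in world meters delimiting the monitored region.
    d_c : float
        Minimum required inter-pedestrian distance in meters (default 2.0).
    u0 : float
        Violation-probability budget in (0, 1); by default tied to the 95%
        interval, U0 = 1 - 0.95^2.
    area_a0 : float, optional
        Override for the ROI area A0 (m^2); computed from the polygon when
        omitted.
    pair_counting : {"unordered", "ordered"}
        Whether each violating pair is counted once or twice (the ordered
        double sum).
    violation_comparison : {"strict", "inclusive"}
        Violation indicator d < d_c (strict, default) or d <= d_c.
    pose_mode : {"bottom", "center"}
        Bounding-box anchor used as the pedestrian pixel position.
    """

    roi_polygon: np.ndarray
    d_c: float = 2.0
    u0: float = DEFAULT_U0
    area_a0: float | None = None
    pair_counting: str = "unordered"
    violation_comparison: str = "strict"
    pose_mode: str = "bottom"
    pedestrian_label: str = DEFAULT_PEDESTRIAN_LABEL

    _polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.roi_polygon = np.asarray(self.roi_polygon, dtype=float)
        self._polygon = _as_polygon(self.roi_polygon)
        if self.area_a0 is None:
            self.area_a0 = float(self._polygon.area)
        if self.area_a0 <= 0.0:
            raise ValueError("ROI area A0 must be positive")
        if self.d_c <= 0.0:
            raise ValueError("minimum distance d_c must be positive")
        if not 0.0 < self.u0 < 1.0:
            raise ValueError("U0 must lie in (0, 1)")
        if self.pair_counting not in ("unordered", "ordered"):
            raise ValueError(f"unknown pair_counting {self.pair_counting!r}")
        if self.violation_comparison not in ("strict", "inclusive"):
            raise ValueError(
                f"unknown violation_comparison {self.violation_comparison!r}"
            )
        if self.pose_mode not in ("bottom", "center"):
            raise ValueError(f"unknown pose_mode {self.pose_mode!r}")


@dataclass
class FrameStats:
    """Distancing summary of one frame.

    ``d_avg`` is NaN when fewer than two pedestrians are present and
    ``r_v`` is NaN for an empty ROI; downstream error metrics skip NaN
    frames rather than imputing zeros.
    """

    frame_id: int
    t: float
    n: int
    rho: float
    distances: np.ndarray
    d_min_per_ped: np.ndarray
    d_avg: float
    v: int
    r_v: float

    @property
    def d_min_overall(self) -> float:
        """Smallest pairwise distance in the frame (NaN if n < 2)."""
        return float(self.distances.min()) if self.distances.size else math.nan


def pairwise_distances(points) -> np.ndarray:
    """All unordered pairwise Euclidean distances, lexicographic pair order.

    The order is (d_12, ..., d_1n, d_23, ..., d_2n, ..., d_{n-1,n}); fewer
    than two points give an empty array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        return np.empty(0)
    return pdist(pts)


def count_violations(
    distances,
    d_c: float,
    pair_counting: str = "unordered",
    violation_comparison: str = "strict",
) -> int:
    """Number of social-distancing violations v among pairwise distances.

    With the default conventions a violation is an unordered pair at
    distance strictly below d_c; ``pair_counting="ordered"`` doubles the
    count (the literal double sum over i and j != i), and
    ``violation_comparison="inclusive"`` uses d <= d_c.
    """
    if d_c <= 0.0:
        raise ValueError("d_c must be positive")
    d = np.asarray(distances, dtype=float)
    if violation_comparison == "strict":
        base = int(np.count_nonzero(d < d_c))
    elif violation_comparison == "inclusive":
        base = int(np.count_nonzero(d <= d_c))
    else:
        raise ValueError(f"unknown violation_comparison {violation_comparison!r}")
    if pair_counting == "unordered":
        return base
    if pair_counting == "ordered":
        return 2 * base
    raise ValueError(f"unknown pair_counting {pair_counting!r}")


def social_density(n: int, area_a0: float) -> float:
    """Social density rho = n / A0 in pedestrians per square meter."""
    if area_a0 <= 0.0:
        raise ValueError("ROI area A0 must be positive")
    if n < 0:
        raise ValueError("pedestrian count must be non-negative")
    return n / area_a0


def _min_per_pedestrian(distances: np.ndarray, n: int) -> np.ndarray:
    """Each pedestrian's distance to their nearest neighbour."""
    if n < 2:
        return np.empty(0)
    full = squareform(distances)
    np.fill_diagonal(full, np.inf)
    return full.min(axis=1)


def stats_from_world_points(
    points_world,
    cfg: SceneConfig,
    frame_id: int = 0,
    t: float = 0.0,
    apply_roi: bool = True,
) -> FrameStats:
    """Compute :class:`FrameStats` directly from world-coordinate positions.

    This is the common tail of the pipeline, shared by image-domain
    analysis and by ground-truth evaluation of simulated scenes.
    """
    pts = np.asarray(points_world, dtype=float).reshape(-1, 2)
    if apply_roi:
        pts = pts[_roi_mask(pts, cfg._polygon)]
    n = len(pts)
    dists = pairwise_distances(pts)
    v = count_violations(
        dists, cfg.d_c, cfg.pair_counting, cfg.violation_comparison
    )
    d_min = _min_per_pedestrian(dists, n)
    return FrameStats(
        frame_id=frame_id,
        t=t,
        n=n,
        rho=social_density(n, cfg.area_a0),
        distances=dists,
        d_min_per_ped=d_min,
        d_avg=float(d_min.mean()) if n >= 2 else math.nan,
        v=v,
        r_v=v / n if n > 0 else math.nan,
    )


def analyze_frame(
    frame: Frame,
    h: Homography,
    cfg: SceneConfig,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> FrameStats:
    """Full per-frame analysis: detections -> world positions -> statistics.

    Pedestrian detections are filtered by label and confidence, anchored at
    the configured bounding-box point, back-projected to the ground plane
    through the homography, restricted to the ROI, and summarized.  A
    detection whose anchor back-projects to the horizon is dropped with a
    warning rather than aborting the frame.
    """
    peds = filter_pedestrians(frame, score_threshold, cfg.pedestrian_label)
    world = []
    for det in peds:
        pose = pixel_pose(det.box, cfg.pose_mode)
        try:
            world.append(image_to_world(h, pose))
        except UnmappablePointError:
            logger.warning(
                "frame %d: detection at pixel (%.1f, %.1f) maps to the "
                "horizon; dropped",
                frame.frame_id, pose[0], pose[1],
            )
    pts = np.asarray(world).reshape(-1, 2)
    return stats_from_world_points(
        pts, cfg, frame_id=frame.frame_id, t=frame.t, apply_roi=True
    )
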