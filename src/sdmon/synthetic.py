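"""Synthetic crowd scenes with a known ground truth.

Generates pedestrian ground-plane positions inside a region of interest and
the corresponding noisy image-domain detections through a known perspective
homography, so every pipeline stage — bounding-box parsing, inverse
perspective mapping, ROI filtering, violation statistics, and the critical
density estimator — can be exercised without video data or a trained
detector.

What the generator emulates
---------------------------
* a time-varying expected pedestrian count (Poisson-distributed per frame),
  as in surveillance footage of streets, malls and station concourses;
* social grouping: a configurable fraction of pedestrians is placed in
  tight Gaussian clusters, which induces distancing violations at moderate
  densities the way real companion groups do;
* perspective projection: a synthetic camera with a plausible oblique view
  (people higher in the image are farther away and their boxes smaller);
* detector imperfections: Gaussian pixel noise on box corners, random
  missed detections, and spurious false-positive boxes.

Frames are mutually independent — there are no pedestrian dynamics, because
every downstream statistic is per-frame.  All randomness flows from a
single seed, split into a *scene* stream and a *detector* stream so that
the same seed yields identical ground truth under different detector-noise
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .detection import BoundingBox, Detection, Frame
from .geometry import Homography, estimate_homography, world_to_image
from .metrics import FrameStats, SceneConfig, stats_from_world_points

__all__ = [
    "SimulationConfig",
    "SimulatedFrame",
    "constant_profile",
    "sinusoid_profile",
    "default_camera_homography",
    "simulate_frames",
    "simulate_regression_data",
]

#: Default 20 m x 20 m ROI (A0 = 400 m^2), the scale of a monitored plaza.
DEFAULT_ROI = ((0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0))


def constant_profile(lam: float) -> Callable[[float], float]:
    """Constant expected pedestrian count lambda(t) = lam."""
    return lambda t: lam


def sinusoid_profile(
    mean: float = 8.0, amplitude: float = 6.0, period_s: float = 60.0
) -> Callable[[float], float]:
    """Sinusoidal expected count, emulating ebb and flow of foot traffic.

    lambda(t) = mean + amplitude * sin(2 pi t / period); the default swings
    between ~2 and ~14 pedestrians in the ROI, i.e. densities up to
    ~0.035 /m^2 on the default 400 m^2 region.
    """
    if amplitude > mean:
        raise ValueError("amplitude must not exceed mean (lambda >= 0)")
    return lambda t: mean + amplitude * np.sin(2.0 * np.pi * t / period_s)


def default_camera_homography() -> Homography:
    """A plausible oblique surveillance camera over the default ROI.

    Maps the 20 m x 20 m ground square onto a trapezoid of a 1920x1080
    image: the near edge spans ~1200 px at the frame bottom, the far edge
    ~580 px higher up, giving ~29-60 px per meter.
    """
    world = [(0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0)]
    image = [(360.0, 1000.0), (1560.0, 1000.0), (1250.0, 330.0), (670.0, 330.0)]
    return estimate_homography(world, image)


@dataclass
class SimulationConfig:
    """Scene and detector parameters of the synthetic generator.

    Defaults describe a moderately busy town-square camera: a 400 m^2 ROI,
    a sinusoidal mean count between ~2 and ~14 pedestrians, half of them in
    companion clusters (mean size 3, spread 0.7 m), a 2 m distancing
    threshold, 2 px detection noise, a 5% miss rate and 0.2 spurious
    detections per frame.
    """

    roi_polygon: Sequence = DEFAULT_ROI
    n_frames: int = 500
    fps: float = 5.0
    lambda_profile: Callable[[float], float] | float = field(
        default_factory=sinusoid_profile
    )
    group_fraction: float = 0.5
    group_size_mean: float = 3.0
    group_spread_sigma: float = 0.7
    homography: Homography | None = None
    image_size: tuple[int, int] = (1080, 1920)  # (H, W) px
    box_height_base: float = 20.0  # px at image row 0
    box_height_per_row: float = 0.13  # px of height per px of row
    box_aspect: float = 0.4  # width / height
    pixel_noise_sigma: float = 2.0
    miss_prob: float = 0.05
    false_positive_rate: float = 0.2
    d_c: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("group_fraction", "miss_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("group_spread_sigma", "pixel_noise_sigma",
                     "false_positive_rate"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.group_size_mean < 2.0:
            raise ValueError("group_size_mean must be >= 2")
        if self.fps <= 0.0 or self.d_c <= 0.0:
            raise ValueError("fps and d_c must be positive")
        if self.homography is None:
            self.homography = default_camera_homography()
        if not callable(self.lambda_profile):
            self.lambda_profile = constant_profile(float(self.lambda_profile))

    def scene_config(self, **overrides) -> SceneConfig:
        """The SceneConfig matching this simulation (same ROI and d_c)."""
        kwargs = {"roi_polygon": self.roi_polygon, "d_c": self.d_c}
        kwargs.update(overrides)
        return SceneConfig(**kwargs)


@dataclass
class SimulatedFrame:
    """One simulated frame: noisy detections plus their ground truth."""

    frame: Frame  # noisy image-domain detections
    truth_frame: Frame  # noise-free boxes of the true pedestrians
    truth_world: np.ndarray  # (n, 2) true ground-plane positions, meters
    truth_stats: FrameStats  # statistics computed directly from truth_world


def _uniform_in_polygon(
    rng: np.random.Generator, poly: Polygon, n: int
) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(4 * (n - filled), 2))
        keep = cand[shapely.covers(poly, shapely.points(cand))]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _place_pedestrians(
    rng: np.random.Generator, cfg: SimulationConfig, poly: Polygon, count: int
) -> np.ndarray:
    """Mix of uniform singletons and Gaussian companion clusters in the ROI."""
    if count == 0:
        return np.empty((0, 2))
    n_grouped = rng.binomial(count, cfg.group_fraction)
    points = [_uniform_in_polygon(rng, poly, count - n_grouped)]
    remaining = n_grouped
    while remaining > 0:
        size = min(2 + rng.poisson(cfg.group_size_mean - 2.0), remaining)
        center = _uniform_in_polygon(rng, poly, 1)[0]
        members = np.tile(center, (size, 1))
        pending = np.ones(size, dtype=bool)
        # rejection-resample cluster members that fall outside the ROI;
        # after the retry cap the stragglers stay at the (interior) center
        for _ in range(200):
            if not pending.any():
                break
            cand = center + rng.normal(
                0.0, cfg.group_spread_sigma, (int(pending.sum()), 2)
            )
            ok = shapely.covers(poly, shapely.points(cand))
            idx = np.flatnonzero(pending)
            members[idx[ok]] = cand[ok]
            pending[idx[ok]] = False
        points.append(members)
        remaining -= size
    return np.concatenate(points, axis=0)


def _box_from_bottom_midpoint(
    cfg: SimulationConfig, u: float, v: float
) -> BoundingBox:
    """Synthesize a pedestrian box from its bottom midpoint via the
    affine height-vs-row model (boxes shrink higher in the image)."""
    h_px = max(cfg.box_height_base + cfg.box_height_per_row * v, 4.0)
    w_px = cfg.box_aspect * h_px
    return BoundingBox(u - 0.5 * w_px, v - h_px, u + 0.5 * w_px, v)


def _noisy_box(
    rng: np.random.Generator, box: BoundingBox, sigma: float
) -> BoundingBox:
    coords = np.array([box.x_min, box.y_min, box.x_max, box.y_max])
    coords = coords + sigma * rng.standard_normal(4)
    x0, x1 = sorted((coords[0], coords[2]))
    y0, y1 = sorted((coords[1], coords[3]))
    return BoundingBox(x0, y0, x1, y1)


def simulate_frames(cfg: SimulationConfig) -> list[SimulatedFrame]:
    """Generate the full simulated sequence.

    Per frame: the pedestrian count is Poisson with mean lambda(t); truth
    positions are placed in the ROI (uniform singletons plus Gaussian
    clusters); each truth point is projected world->image as a box bottom
    midpoint and dressed with a synthetic box; corners are perturbed with
    Gaussian pixel noise; each detection is dropped with the miss
    probability; Poisson-many false positives are scattered over the lower
    image.  Deterministic under a fixed seed.
    """
    rng_scene, rng_det = np.random.default_rng(cfg.seed).spawn(2)
    poly = Polygon(np.asarray(cfg.roi_polygon, dtype=float))
    scene_cfg = cfg.scene_config()
    h_img, w_img = cfg.image_size
    frames: list[SimulatedFrame] = []

    for k in range(cfg.n_frames):
        t = k / cfg.fps
        lam = max(float(cfg.lambda_profile(t)), 0.0)
        count = int(rng_scene.poisson(lam))
        truth_world = _place_pedestrians(rng_scene, cfg, poly, count)

        truth_dets: list[Detection] = []
        noisy_dets: list[Detection] = []
        for p in truth_world:
            u, v = world_to_image(cfg.homography, p)
            box = _box_from_bottom_midpoint(cfg, u, v)
            truth_dets.append(Detection("person", box, 1.0))
            noisy = _noisy_box(rng_det, box, cfg.pixel_noise_sigma)
            score = float(rng_det.uniform(0.7, 1.0))
            missed = rng_det.random() < cfg.miss_prob
            if not missed:
                noisy_dets.append(Detection("person", noisy, score))

        n_fp = int(rng_det.poisson(cfg.false_positive_rate))
        for _ in range(n_fp):
            u = float(rng_det.uniform(0.0, w_img))
            v = float(rng_det.uniform(0.35 * h_img, h_img))
            box = _box_from_bottom_midpoint(cfg, u, v)
            noisy_dets.append(
                Detection("person", box, float(rng_det.uniform(0.5, 0.9)))
            )

        frames.append(
            SimulatedFrame(
                frame=Frame(k, t, noisy_dets, cfg.image_size),
                truth_frame=Frame(k, t, truth_dets, cfg.image_size),
                truth_world=truth_world,
                truth_stats=stats_from_world_points(
                    truth_world, scene_cfg, frame_id=k, t=t
                ),
            )
        )
    return frames


def simulate_regression_data(
    beta0: float = 0.02,
    beta1: float = 0.004,
    noise_sigma: float = 0.003,
    v_range: tuple[int, int] = (0, 10),
    n_points: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (v, rho) pairs directly from the linear generative model.

    v is uniform on the integer range ``v_range`` (inclusive) and
    rho = beta0 + beta1 * v + Normal(0, noise_sigma^2).  Exercises the
    critical-density estimator with known truth.
    """
    if noise_sigma < 0.0:
        raise ValueError("noise_sigma must be non-negative")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    lo, hi = v_range
    if hi < lo:
        raise ValueError("empty v_range")
    rng = np.random.default_rng(seed)
    v = rng.integers(lo, hi + 1, size=n_points).astype(float)
    rho = beta0 + beta1 * v + rng.normal(0.0, noise_sigma, size=n_points)
    return v, rho
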