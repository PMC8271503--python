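"""Detector output containers, ground-point extraction, and the detector plug-in contract.

The monitoring pipeline is detector-agnostic: any object detector that maps
an image to ``(label, bounding box, score)`` tuples can drive it, whether
the detections arrive from a file or from a live callable.  Only the
``"person"`` class is consumed downstream; a pedestrian's ground contact
point is taken as the midpoint of the bottom edge of its bounding box (the
box centroid is available as a comparison variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "Detection",
    "Frame",
    "Detector",
    "pixel_pose",
    "filter_pedestrians",
    "frames_from_detector",
    "DEFAULT_SCORE_THRESHOLD",
    "DEFAULT_PEDESTRIAN_LABEL",
]

DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_PEDESTRIAN_LABEL = "person"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates (v grows downward)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min <= self.x_max and self.y_min <= self.y_max):
            raise ValueError(
                f"invalid box extents ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @classmethod
    def from_corners(cls, corners: Sequence[Sequence[float]]) -> "BoundingBox":
        """Build from the four-corner tuple (top-left, top-right,
        bottom-left, bottom-right); only axis-aligned boxes are supported."""
        pts = np.asarray(corners, dtype=float)
        if pts.shape != (4, 2):
            raise ValueError("expected 4 (x, y) corners")
        return cls(
            float(pts[:, 0].min()), float(pts[:, 1].min()),
            float(pts[:, 0].max()), float(pts[:, 1].max()),
        )


@dataclass(frozen=True)
class Detection:
    """One detector output: class label, box, and confidence score."""

    label: str
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class Frame:
    """All detections of one camera frame at time ``t`` (seconds)."""

    frame_id: int
    t: float
    detections: list[Detection] = field(default_factory=list)
    image_size: tuple[int, int] | None = None  # (H, W) pixels

    def __post_init__(self) -> None:
        if self.frame_id < 0:
            raise ValueError("frame_id must be non-negative")
        if not np.isfinite(self.t):
            raise ValueError("timestamp must be finite")


def pixel_pose(box: BoundingBox, mode: str = "bottom") -> np.ndarray:
    """Pixel position representing a pedestrian's ground contact.

    ``"bottom"`` returns the midpoint of the box's bottom edge — the point
    where the feet meet the ground plane, which is what the inverse
    perspective mapping assumes.  ``"center"`` returns the box centroid,
    a comparison variant that sits above the ground plane and therefore
    back-projects with a systematic bias.
    """
    u = 0.5 * (box.x_min + box.x_max)
    if mode == "bottom":
        return np.array([u, box.y_max])
    if mode == "center":
        return np.array([u, 0.5 * (box.y_min + box.y_max)])
    raise ValueError(f"unknown pose mode {mode!r} (expected 'bottom' or 'center')")


def filter_pedestrians(
    frame: Frame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    label: str = DEFAULT_PEDESTRIAN_LABEL,
) -> list[Detection]:
    """Detections of the pedestrian class at or above the confidence threshold.

    Input order is preserved and the frame is not mutated; the threshold is
    inclusive (score == threshold is kept).
    """
    return [
        d
        for d in frame.detections
        if d.label == label and d.score >= score_threshold
    ]


class Detector(Protocol):
    """Plug-in contract for external detectors.

    Any callable mapping an opaque image handle to a list of
    :class:`Detection` conforms; the pipeline treats its output exactly as
    it treats file-loaded detections.  Exceptions raised by the callable
    propagate as detector failures.
    """

    def __call__(self, image: Any) -> list[Detection]: ...


def frames_from_detector(
    detector: Callable[[Any], list[Detection]],
    images: Sequence[Any],
    timestamps: Sequence[float] | None = None,
    image_size: tuple[int, int] | None = None,
) -> list[Frame]:
    """Run a conforming detector over images and wrap the outputs as frames.

    ``timestamps`` defaults to the image index in seconds.  The resulting
    frames are indistinguishable from file-loaded ones downstream.
    """
    if timestamps is None:
        timestamps = [float(i) for i in range(len(images))]
    if len(timestamps) != len(images):
        raise ValueError("timestamps and images must have equal length")
    return [
        Frame(frame_id=i, t=float(t), detections=list(detector(img)),
              image_size=image_size)
        for i, (img, t) in enumerate(zip(images, timestamps))
    ]
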