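"""File dialects and end-to-end pipeline composition.

Formats
-------
Detection table (CSV): one row per detection with header
``frame_id,t_seconds,x_min,y_min,x_max,y_max,label,score``; pixel
coordinates may be fractional (sub-pixel detector output).  A JSON
equivalent stores a list of frame objects.  Frames are grouped by
``frame_id`` and sorted; within a frame, file order is preserved.  Frames
with no detections can be declared in JSON; in CSV they are implicit (a
frame id simply has no rows) unless listed with an empty label.

Stats table (CSV): one row per frame with columns
``frame_id,t,n,rho,v,r_v,d_avg,d_min_overall,c1,c2``; undefined values
(e.g. d_avg with fewer than two pedestrians) are empty fields.

ROI file (JSON): ``{"polygon_m": [[x, y], ...], "area_m2_override": null}``.

Only aggregate statistics are ever written — no imagery and no
per-individual trajectories, so the emitted artifacts contain no personal
information.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .control import control_signals
from .critical_density import (
    CriticalDensityResult,
    FitError,
    estimate_critical_density,
)
from .detection import BoundingBox, Detection, Frame
from .geometry import Homography, estimate_homography
from .metrics import FrameStats, SceneConfig, analyze_frame

__all__ = [
    "read_detections",
    "write_detections",
    "read_roi",
    "write_roi",
    "read_correspondences",
    "stats_to_frame",
    "stats_table",
    "write_stats",
    "read_stats",
    "report_to_dict",
    "write_report",
    "analyze_frames",
]

DETECTION_COLUMNS = [
    "frame_id", "t_seconds", "x_min", "y_min", "x_max", "y_max",
    "label", "score",
]
STATS_COLUMNS = [
    "frame_id", "t", "n", "rho", "v", "r_v", "d_avg", "d_min_overall",
    "c1", "c2",
]


class ParseError(ValueError):
    """An input table does not conform to its dialect."""


def read_detections(path) -> list[Frame]:
    """Read a detection table (CSV or JSON by extension) into frames.

    Frames are returned sorted by ``frame_id``; detections keep their file
    order within a frame.  Malformed rows raise :class:`ParseError` naming
    the offending row.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_detections_json(path)
    return _read_detections_csv(path)


def _read_detections_csv(path: Path) -> list[Frame]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    numeric = [c for c in DETECTION_COLUMNS if c != "label"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col!r} in data row {bad[0] + 1}"
            )
        df[col] = coerced
    frames: dict[int, Frame] = {}
    for row in df.itertuples():
        fid = int(row.frame_id)
        frame = frames.setdefault(fid, Frame(fid, float(row.t_seconds)))
        if pd.isna(row.label) or row.label == "":
            continue  # frame declared with no detections
        try:
            box = BoundingBox(row.x_min, row.y_min, row.x_max, row.y_max)
            det = Detection(str(row.label), box, float(row.score))
        except ValueError as exc:
            raise ParseError(f"{path}: data row {row.Index + 1}: {exc}")
        frame.detections.append(det)
    return [frames[fid] for fid in sorted(frames)]


def _read_detections_json(path: Path) -> list[Frame]:
    with open(path) as fh:
        payload = json.load(fh)
    frames = []
    for i, obj in enumerate(payload):
        try:
            dets = [
                Detection(
                    d["label"],
                    BoundingBox(d["x_min"], d["y_min"], d["x_max"], d["y_max"]),
                    d["score"],
                )
                for d in obj.get("detections", [])
            ]
            frames.append(
                Frame(int(obj["frame_id"]), float(obj["t_seconds"]), dets)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: frame object {i}: {exc}")
    return sorted(frames, key=lambda f: f.frame_id)


def write_detections(path, frames: list[Frame]) -> None:
    """Write frames as a detection table (CSV or JSON by extension).

    Round-trips losslessly through :func:`read_detections` up to float
    formatting; frames without detections are preserved (empty-label row in
    CSV, empty list in JSON).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "frame_id": f.frame_id,
                "t_seconds": f.t,
                "detections": [
                    {
                        "label": d.label,
                        "x_min": d.box.x_min, "y_min": d.box.y_min,
                        "x_max": d.box.x_max, "y_max": d.box.y_max,
                        "score": d.score,
                    }
                    for d in f.detections
                ],
            }
            for f in frames
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    rows = []
    for f in frames:
        if not f.detections:
            rows.append((f.frame_id, f.t, "", "", "", "", "", ""))
        for d in f.detections:
            rows.append(
                (f.frame_id, f.t, d.box.x_min, d.box.y_min, d.box.x_max,
                 d.box.y_max, d.label, d.score)
            )
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_roi(path) -> tuple[np.ndarray, float | None]:
    """Read the ROI JSON; returns (polygon vertices, optional A0 override)."""
    with open(path) as fh:
        payload = json.load(fh)
    poly = np.asarray(payload["polygon_m"], dtype=float)
    return poly, payload.get("area_m2_override")


def write_roi(path, polygon, area_override: float | None = None) -> None:
    payload = {
        "polygon_m": np.asarray(polygon, dtype=float).tolist(),
        "area_m2_override": area_override,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_correspondences(path) -> tuple[np.ndarray, np.ndarray]:
    """Read calibration key points (CSV or JSON) as (world, image) arrays.

    CSV columns: ``world_x_m, world_y_m, image_u_px, image_v_px``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        arr = np.asarray(
            [[r["world_x_m"], r["world_y_m"], r["image_u_px"], r["image_v_px"]]
             for r in rows],
            dtype=float,
        )
    else:
        df = pd.read_csv(path)
        cols = ["world_x_m", "world_y_m", "image_u_px", "image_v_px"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        arr = df[cols].to_numpy(float)
    return arr[:, :2], arr[:, 2:]


def stats_table(
    stats: list[FrameStats], signals: list | None = None
) -> pd.DataFrame:
    """Per-frame stats as a DataFrame in the standard column layout."""
    rows = []
    for i, st in enumerate(stats):
        sig = signals[i] if signals is not None else None
        rows.append(
            {
                "frame_id": st.frame_id,
                "t": st.t,
                "n": st.n,
                "rho": st.rho,
                "v": st.v,
                "r_v": st.r_v,
                "d_avg": st.d_avg,
                "d_min_overall": st.d_min_overall,
                "c1": sig.c1 if sig is not None else np.nan,
                "c2": sig.c2 if sig is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def write_stats(path, table: pd.DataFrame) -> None:
    """Write a stats table as CSV with undefined values as empty fields."""
    table.to_csv(path, index=False)


def read_stats(path) -> pd.DataFrame:
    """Read a stats CSV back; empty fields become NaN."""
    df = pd.read_csv(path)
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def report_to_dict(result: CriticalDensityResult) -> dict:
    """JSON-ready critical-density regression report."""
    fit = result.fit
    return {
        "beta0": fit.beta0,
        "beta1": fit.beta1,
        "s": fit.s,
        "n_obs": fit.n_obs,
        "rho_c": result.rho_c,
        "pi_lower": result.pi_lower,
        "pi_upper": result.pi_upper,
        "level": result.level,
        "skewness_rho": None
        if math.isnan(result.skewness_rho)
        else result.skewness_rho,
    }


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


def analyze_frames(
    frames: list[Frame],
    h: Homography,
    cfg: SceneConfig,
    score_threshold: float = 0.5,
    level: float = 0.95,
) -> tuple[pd.DataFrame, CriticalDensityResult | None, FitError | None]:
    """Run the full offline pipeline over a detection sequence.

    Computes per-frame statistics, fits the density-on-violations
    regression over all frames with a defined density, derives the critical
    density, and evaluates the per-frame control signals against it.
    Returns the stats table (with c1/c2 columns), the critical-density
    result, and the fit error if the regression was degenerate (e.g. every
    frame violation-free), in which case c2 is evaluated against rho_c = 0.
    """
    stats = [analyze_frame(f, h, cfg, score_threshold) for f in frames]
    result: CriticalDensityResult | None = None
    fit_error: FitError | None = None
    try:
        result = estimate_critical_density(
            [s.v for s in stats], [s.rho for s in stats], level=level
        )
    except FitError as exc:
        fit_error = exc
    rho_c = result.rho_c if result is not None else 0.0
    signals = [control_signals(s, rho_c, cfg.d_c) for s in stats]
    return stats_table(stats, signals), result, fit_error
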