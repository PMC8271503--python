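"""Frame-level evaluation of distancing statistics against ground truth.

Predicted and ground-truth per-frame series are aligned by frame id and
compared by mean absolute error (for the average closest distance d_avg,
the violation ratio r_v, and the violation count v) and by a frame-level
confusion matrix for violation *detection*, where a frame is positive iff
it contains at least one violation (v > 0).  Precision, recall and accuracy
are reported as percentages rounded to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "mae",
    "violation_confusion",
    "precision_recall_accuracy",
    "evaluate_stats",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Frame counts of violation detection vs ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _align(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    """Align two per-frame series on their frame-id index.

    Plain sequences are treated as already aligned positionally; pandas
    Series are joined on their index so only shared frames are compared.
    """
    if isinstance(pred, pd.Series) or isinstance(gt, pd.Series):
        pred = pd.Series(pred) if not isinstance(pred, pd.Series) else pred
        gt = pd.Series(gt) if not isinstance(gt, pd.Series) else gt
        joined = pd.concat([pred, gt], axis=1, join="inner")
        return joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError(
            f"series are misaligned: {p.shape} vs {g.shape} frames"
        )
    return p, g


def mae(pred, gt) -> float:
    """Mean absolute error over frames where both series are defined.

    Frames where either side is NaN (e.g. d_avg in a frame with fewer than
    two pedestrians) are skipped rather than imputed.

    Raises
    ------
    ValueError
        If no frame has both values defined.
    """
    p, g = _align(pred, gt)
    keep = np.isfinite(p) & np.isfinite(g)
    if not keep.any():
        raise ValueError("no overlapping defined frames to compare")
    return float(np.mean(np.abs(p[keep] - g[keep])))


def violation_confusion(pred_v, gt_v) -> ConfusionMatrix:
    """Frame-level violation-detection confusion matrix.

    A frame is positive iff its violation count is > 0; ground truth is the
    reference side.
    """
    p, g = _align(pred_v, gt_v)
    keep = np.isfinite(p) & np.isfinite(g)
    pp, gp = p[keep] > 0, g[keep] > 0
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pp & gp)),
        fp=int(np.count_nonzero(pp & ~gp)),
        fn=int(np.count_nonzero(~pp & gp)),
        tn=int(np.count_nonzero(~pp & ~gp)),
    )


def precision_recall_accuracy(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Precision, recall and accuracy as percentages (2-decimal rounding).

    A metric with a zero denominator is returned as NaN rather than raising.
    """
    precision = (
        100.0 * cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else math.nan
    )
    recall = (
        100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else math.nan
    )
    accuracy = (
        100.0 * (cm.tp + cm.tn) / cm.total if cm.total > 0 else math.nan
    )
    return (round(precision, 2), round(recall, 2), round(accuracy, 2))


def evaluate_stats(pred: pd.DataFrame, gt: pd.DataFrame) -> dict:
    """Full evaluation report from two per-frame stats tables.

    Both tables use the standard stats layout (columns ``frame_id``, ``n``,
    ``v``, ``r_v``, ``d_avg``, ...).  Returns a JSON-ready dict with the
    MAE of d_avg (meters), of the violation ratio, and of the violation
    count, plus the confusion matrix and the detection percentages.
    """
    p = pred.set_index("frame_id")
    g = gt.set_index("frame_id")
    report: dict = {
        "n_frames": int(p.index.intersection(g.index).size),
        "mae_davg_m": mae(p["d_avg"], g["d_avg"]),
        "mae_rv": mae(p["r_v"], g["r_v"]),
        "mae_v": mae(p["v"], g["v"]),
    }
    cm = violation_confusion(p["v"], g["v"])
    prec, rec, acc = precision_recall_accuracy(cm)
    report["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
    report["precision_pct"] = prec
    report["recall_pct"] = rec
    report["accuracy_pct"] = acc
    return report
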