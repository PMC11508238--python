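"""Detection metrics (IoU, AP, mAP) and counting metrics.

AP follows the 101-point interpolated convention: detections are sorted
by descending confidence and greedily matched one-to-one to ground truth
within the same frame at the given IoU threshold; interpolated precision
at recall level r is the maximum precision attained at any recall >= r;
AP is the mean of interpolated precision over r in {0, 0.01, ..., 1}.
mAP averages AP over the ten IoU thresholds 0.50, 0.55, ..., 0.95 and
then over categories.

Counting metrics compare per-frame predicted counts with ground truth:
accuracy (% of frames with the rounded prediction exactly equal to
truth), MAE, MRE (relative error, zero-truth frames skipped), MSE and
RMSE.  Error metrics use the raw fractional predictions; only accuracy
rounds (half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError
from .simulate import _box_iou_corners
from .types import CATEGORY_NAMES, BoundingBox, Category, FrameDetections, GroundTruthObject

RECALL_GRID = np.linspace(0.0, 1.0, 101)
MAP_IOU_GRID = np.round(np.arange(10) * 0.05 + 0.50, 2)  # 0.50, 0.55, ..., 0.95


@dataclass
class EvaluationConfig:
    iou_valid_threshold: float = 0.5
    map_iou_grid: np.ndarray = field(default_factory=lambda: MAP_IOU_GRID.copy())
    recall_grid: np.ndarray = field(default_factory=lambda: RECALL_GRID.copy())
    rounding: Literal["half-up"] = "half-up"
    mre_zero_policy: Literal["skip-zero-truth"] = "skip-zero-truth"


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    return _box_iou_corners(a, b)


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer with .5 going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# Detection metrics
# ---------------------------------------------------------------------------

def _greedy_match_flags(
    detections: Sequence[tuple[int, BoundingBox, float]],
    truth: Sequence[tuple[int, BoundingBox]],
    iou_threshold: float,
) -> tuple[np.ndarray, int]:
    """Sort detections by descending confidence and greedily match each to
    the best-overlapping unmatched truth box in the same frame.  Returns
    (tp_flags in sorted order, number of truth boxes)."""
    order = sorted(range(len(detections)), key=lambda k: -detections[k][2])
    truth_by_frame: dict[int, list[int]] = {}
    for t_idx, (fi, _) in enumerate(truth):
        truth_by_frame.setdefault(fi, []).append(t_idx)
    matched = np.zeros(len(truth), dtype=bool)
    tp = np.zeros(len(detections), dtype=bool)
    for rank, k in enumerate(order):
        fi, box, _ = detections[k]
        best_iou, best_t = 0.0, -1
        for t_idx in truth_by_frame.get(fi, []):
            if matched[t_idx]:
                continue
            ov = _box_iou_corners(box, truth[t_idx][1])
            if ov >= iou_threshold and ov > best_iou:
                best_iou, best_t = ov, t_idx
        if best_t >= 0:
            matched[best_t] = True
            tp[rank] = True
    return tp, len(truth)


def average_precision(
    detections: Sequence[tuple[int, BoundingBox, float]],
    truth: Sequence[tuple[int, BoundingBox]],
    iou_threshold: float = 0.5,
    recall_grid: np.ndarray = RECALL_GRID,
) -> float:
    """101-point interpolated AP for one category.

    ``detections`` are (frame_index, box, confidence) triples; ``truth``
    are (frame_index, box) pairs.  With no truth boxes AP is defined as 0.
    """
    if len(truth) == 0 or len(detections) == 0:
        return 0.0
    tp, n_truth = _greedy_match_flags(detections, truth, iou_threshold)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_truth
    # max precision at recall >= r, computed right-to-left
    prec_interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in recall_grid:
        idx = np.searchsorted(recall, r, side="left")
        ap += prec_interp[idx] if idx < len(recall) else 0.0
    return float(ap / len(recall_grid))


def mean_average_precision(
    detections: Sequence[FrameDetections],
    truth: Sequence[GroundTruthObject],
    config: EvaluationConfig | None = None,
) -> dict:
    """Per-category AP across the IoU grid plus the headline mAP.

    A category absent from both truth and detections is excluded from the
    category mean.
    """
    config = config or EvaluationConfig()
    det_by_cat: dict[int, list[tuple[int, BoundingBox, float]]] = {int(c): [] for c in Category}
    for frame in detections:
        for det in frame.detections:
            det_by_cat[int(det.category)].append((frame.frame_index, det.box, det.confidence))
    truth_by_cat: dict[int, list[tuple[int, BoundingBox]]] = {int(c): [] for c in Category}
    for obj in truth:
        truth_by_cat[int(obj.category)].append((obj.frame_index, obj.box))

    per_category: dict[str, dict] = {}
    cat_maps = []
    for c in Category:
        dets, tr = det_by_cat[int(c)], truth_by_cat[int(c)]
        if not dets and not tr:
            continue
        aps = {
            float(thr): average_precision(dets, tr, thr, config.recall_grid)
            for thr in config.map_iou_grid
        }
        cat_map = float(np.mean(list(aps.values())))
        per_category[c.label] = {"ap_by_iou": aps, "map": cat_map}
        cat_maps.append(cat_map)
    return {
        "per_category": per_category,
        "map": float(np.mean(cat_maps)) if cat_maps else float("nan"),
    }


# ---------------------------------------------------------------------------
# Counting metrics
# ---------------------------------------------------------------------------

def _align(predicted: pd.DataFrame, truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if len(predicted) != len(truth) or not (predicted.index == truth.index).all():
        raise ValidationError("predicted and truth count tables are not frame-aligned")
    cols = list(CATEGORY_NAMES)
    return predicted[cols].to_numpy(float), truth[cols].to_numpy(float)


def counting_accuracy(
    predicted: pd.DataFrame, truth: pd.DataFrame, config: EvaluationConfig | None = None
) -> dict[str, float]:
    """Percent of frames whose rounded predicted count equals the truth,
    per category."""
    pred, tr = _align(predicted, truth)
    if len(pred) == 0:
        raise ValidationError("empty count tables")
    exact = round_half_up(pred) == tr
    return {
        name: float(100.0 * exact[:, k].mean()) for k, name in enumerate(CATEGORY_NAMES)
    }


def regression_errors(
    predicted: pd.DataFrame, truth: pd.DataFrame, config: EvaluationConfig | None = None
) -> dict[str, dict[str, float]]:
    """MAE, MRE, MSE, RMSE per category on raw (unrounded) predictions.

    MRE averages |y - yhat| / y over frames with y > 0 only; it is NaN for
    a category never present.
    """
    pred, tr = _align(predicted, truth)
    if len(pred) == 0:
        raise ValidationError("empty count tables")
    out: dict[str, dict[str, float]] = {}
    for k, name in enumerate(CATEGORY_NAMES):
        err = tr[:, k] - pred[:, k]
        mae = float(np.mean(np.abs(err)))
        mse = float(np.mean(err**2))
        pos = tr[:, k] > 0
        mre = float(np.mean(np.abs(err[pos]) / tr[pos, k])) if pos.any() else float("nan")
        out[name] = {"mae": mae, "mre": mre, "mse": mse, "rmse": float(np.sqrt(mse))}
    return out
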