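"""Classification metrics, mask IoU, AP / mAP, and CV aggregation.

AP uses greedy confidence-ranked matching (each ground truth matched at
most once, a match requiring IoU at or above the threshold) and 101-point
interpolation of the precision-recall curve, the convention behind
"mAP@0.5:0.95".  Detection entries may be binary masks or ``(r0, c0, r1,
c1)`` boxes; a single positive class is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from cytocluster.errors import RegistrationError, UndefinedMetricError
from cytocluster.imageio_core import BinaryMask

__all__ = [
    "ConfusionCounts",
    "DetectionSet",
    "accuracy",
    "precision_recall_f1",
    "iou",
    "average_precision",
    "map_range",
    "aggregate_cv",
    "MAP_THRESHOLDS",
]

logger = logging.getLogger(__name__)

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; clusters are the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero total count")
    return (c.tp + c.tn) / c.total


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall, and their harmonic mean.

    Any zero denominator yields 0 for that metric (logged as a warning).
    """

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s has zero denominator; reporting 0", name)
            return 0.0
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        logger.warning("f1 has zero denominator; reporting 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


Box = tuple[float, float, float, float]  # (r0, c0, r1, c1), half-open


def iou(a: BinaryMask | Box, b: BinaryMask | Box) -> float:
    """Intersection over union of two masks or two boxes.

    Defined as 1.0 when both operands are empty.
    """
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask):
        if a.grid.shape != b.grid.shape:
            raise RegistrationError(
                f"mask shapes differ: {a.grid.shape} vs {b.grid.shape}"
            )
        inter = int((a.grid & b.grid).sum())
        union = int((a.grid | b.grid).sum())
    else:
        inter = _box_intersection(a, b)
        union = _box_area(a) + _box_area(b) - inter
    return 1.0 if union == 0 else inter / union


def _box_area(box: Box) -> float:
    r0, c0, r1, c1 = box
    return max(0.0, r1 - r0) * max(0.0, c1 - c0)


def _box_intersection(a: Box, b: Box) -> float:
    dr = min(a[2], b[2]) - max(a[0], b[0])
    dc = min(a[3], b[3]) - max(a[1], b[1])
    return max(0.0, dr) * max(0.0, dc)


@dataclass(frozen=True)
class DetectionSet:
    """Scored predictions and ground truths for one evaluation pool."""

    predictions: tuple[tuple[BinaryMask | Box, float], ...]
    truths: tuple[BinaryMask | Box, ...]

    def __post_init__(self) -> None:
        for _, conf in self.predictions:
            if not (0.0 <= conf <= 1.0):
                raise ValueError(f"confidence {conf} outside [0, 1]")


def _match_predictions(d: DetectionSet, iou_thr: float) -> list[bool]:
    """Greedy matching in descending confidence (ties by input order).

    Returns a TP/FP flag per prediction, in the ranked order.
    """
    order = sorted(range(len(d.predictions)), key=lambda i: (-d.predictions[i][1], i))
    matched = [False] * len(d.truths)
    flags: list[bool] = []
    for i in order:
        pred, _ = d.predictions[i]
        best_j, best_iou = -1, 0.0
        for j, truth in enumerate(d.truths):
            if matched[j]:
                continue
            v = iou(pred, truth)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(d: DetectionSet, iou_thr: float) -> float:
    """AP at one IoU threshold, 101-point interpolated."""
    if not (0.0 < iou_thr <= 1.0):
        raise UndefinedMetricError(f"iou_thr must lie in (0, 1], got {iou_thr}")
    if not d.truths:
        raise UndefinedMetricError("average precision undefined without ground truths")
    if not d.predictions:
        return 0.0
    flags = _match_predictions(d, iou_thr)
    tp_cum = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    precisions = tp_cum / ranks
    recalls = tp_cum / len(d.truths)
    # 101-point interpolation: p(r) = max precision at recall >= r
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recalls >= r - 1e-12
        ap += float(precisions[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def map_range(
    d: DetectionSet, thresholds: Sequence[float] = MAP_THRESHOLDS
) -> float:
    """Mean AP over the IoU thresholds (default 0.50:0.95 step 0.05)."""
    return float(np.mean([average_precision(d, t) for t in thresholds]))


def aggregate_cv(
    per_fold_metrics: Sequence[Mapping[str, float]],
) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation (ddof=1) per metric across folds.

    A single fold reports sd = 0 (flagged in the log).
    """
    if not per_fold_metrics:
        raise UndefinedMetricError("need at least one fold")
    keys = list(per_fold_metrics[0])
    out: dict[str, tuple[float, float]] = {}
    single = len(per_fold_metrics) == 1
    if single:
        logger.warning("only one fold supplied; standard deviations reported as 0")
    for key in keys:
        vals = np.array([m[key] for m in per_fold_metrics], dtype=float)
        sd = 0.0 if single else float(np.std(vals, ddof=1))
        out[key] = (float(vals.mean()), sd)
    return out
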