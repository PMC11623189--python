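"""Detection and duration evaluation metrics.

Implements the standard detection-evaluation stack: binary confusion
counts with accuracy / precision / recall / F1, per-class average
precision with all-point (COCO-style) interpolation, mAP at a single IoU
threshold and averaged over the 0.50:0.95:0.05 grid, a K-class identity
confusion matrix, and the mean absolute error of per-individual behavior
durations in minutes.

Multi-class note: with identity classification folded into detection,
"mistaking one individual for another" contributes a false positive to
the predicted class and a false negative to the true class; true
negatives count (detection, non-involved class) pairs. A metric whose
denominator is zero is reported as None (undefined), never silently 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .behavior import DurationSummary

logger = logging.getLogger(__name__)

IOU_GRID = tuple(round(0.5 + 0.05 * k, 2) for k in range(10))  # 0.50 .. 0.95


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    matrix: np.ndarray | None = None  # K x K, true x predicted

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    ap_per_class: dict[int, float] = field(default_factory=dict)
    map50: float | None = None
    map50_95: float | None = None
    n_classes: int = 0
    duration_mae: float | None = None
    undefined: list[str] = field(default_factory=list)


def prf1(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from binary confusion counts.

    accuracy = (TP+TN) / (TP+TN+FP+FN); recall = TP / (TP+FN);
    precision = TP / (TP+FP); F1 = 2TP / (2TP+FP+FN). Undefined metrics
    (zero denominator) come back as None and are listed in ``undefined``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    rep = MetricsReport()
    total = tp + tn + fp + fn
    if total > 0:
        rep.accuracy = (tp + tn) / total
    else:
        rep.undefined.append("accuracy")
    if tp + fn > 0:
        rep.recall = tp / (tp + fn)
    else:
        rep.undefined.append("recall")
    if tp + fp > 0:
        rep.precision = tp / (tp + fp)
    else:
        rep.undefined.append("precision")
    if 2 * tp + fp + fn > 0:
        rep.f1 = 2 * tp / (2 * tp + fp + fn)
    else:
        rep.undefined.append("f1")
    return rep


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise EvaluationError("boxes must have positive size")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


@dataclass(frozen=True)
class BoxPrediction:
    """A scored box with a class label, for AP evaluation."""

    frame: int
    label: int
    box: tuple[float, float, float, float]
    confidence: float


@dataclass(frozen=True)
class BoxTruth:
    frame: int
    label: int
    box: tuple[float, float, float, float]


def _ap_from_pr(recall: np.ndarray, precision: np.ndarray, interpolation: str) -> float:
    if interpolation == "all_point":
        # precision envelope from the right, integrate over recall steps
        r = np.concatenate([[0.0], recall, [1.0]])
        p = np.concatenate([[0.0], precision, [0.0]])
        p = np.maximum.accumulate(p[::-1])[::-1]
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if interpolation == "eleven_point":
        pts = np.linspace(0, 1, 11)
        vals = [precision[recall >= t].max() if np.any(recall >= t) else 0.0 for t in pts]
        return float(np.mean(vals))
    raise EvaluationError(f"unknown interpolation: {interpolation!r}")


def average_precision(
    predictions: list[BoxPrediction],
    ground_truth: list[BoxTruth],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> dict[int, float]:
    """Per-class average precision at one IoU threshold.

    Confidence-sorted greedy matching: each prediction claims the
    highest-IoU unclaimed truth box of its class in its frame, a match
    requiring IoU >= threshold (boundary inclusive). Classes without any
    ground truth have undefined AP and are excluded (logged).
    """
    classes = sorted({t.label for t in ground_truth})
    pred_classes = {p.label for p in predictions}
    for c in sorted(pred_classes - set(classes)):
        logger.info("class %s has predictions but no ground truth; AP undefined", c)
    aps: dict[int, float] = {}
    for c in classes:
        gts = [t for t in ground_truth if t.label == c]
        preds = sorted(
            (p for p in predictions if p.label == c),
            key=lambda p: -p.confidence,
        )
        n_gt = len(gts)
        if not preds:
            aps[c] = 0.0
            continue
        by_frame: dict[int, list[tuple[int, BoxTruth]]] = {}
        for gi, t in enumerate(gts):
            by_frame.setdefault(t.frame, []).append((gi, t))
        claimed: set[int] = set()
        tp = np.zeros(len(preds))
        for k, p in enumerate(preds):
            best, best_iou = -1, iou_threshold
            for gi, t in by_frame.get(p.frame, ()):
                if gi in claimed:
                    continue
                v = iou(p.box, t.box)
                if v >= best_iou:
                    best, best_iou = gi, v
            if best >= 0:
                claimed.add(best)
                tp[k] = 1
        cum_tp = np.cumsum(tp)
        recall = cum_tp / n_gt
        precision = cum_tp / np.arange(1, len(preds) + 1)
        aps[c] = _ap_from_pr(recall, precision, interpolation)
    return aps


def mean_ap(
    predictions: list[BoxPrediction],
    ground_truth: list[BoxTruth],
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> float | None:
    aps = average_precision(predictions, ground_truth, iou_threshold, interpolation)
    if not aps:
        return None
    return float(np.mean(list(aps.values())))


def map_range(
    predictions: list[BoxPrediction],
    ground_truth: list[BoxTruth],
    interpolation: str = "all_point",
) -> tuple[float | None, float | None]:
    """(mAP at IoU 0.5, mean of mAP over the 10-threshold 0.50:0.95 grid)."""
    maps = [
        mean_ap(predictions, ground_truth, t, interpolation) for t in IOU_GRID
    ]
    if any(m is None for m in maps):
        return None, None
    return maps[0], float(np.mean(maps))


def identity_confusion(
    true_labels: list[int], predicted_labels: list[int], n_classes: int
) -> np.ndarray:
    """K x K confusion matrix (rows true, columns predicted)."""
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError("label lists must have equal length")
    M = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        M[t, p] += 1
    return M


def multiclass_counts(matrix: np.ndarray) -> ConfusionCounts:
    """Fold a K-class confusion matrix into binary TP/TN/FP/FN totals.

    Per class c: TP = M[c,c]; FP = column sum minus diagonal; FN = row sum
    minus diagonal; TN = everything not in row or column c. Totals sum
    over classes.
    """
    K = matrix.shape[0]
    total = matrix.sum()
    tp = fp = fn = tn = 0
    for c in range(K):
        tpc = matrix[c, c]
        fpc = matrix[:, c].sum() - tpc
        fnc = matrix[c, :].sum() - tpc
        tp += tpc
        fp += fpc
        fn += fnc
        tn += total - tpc - fpc - fnc
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn), matrix=matrix)


def duration_mae(
    estimated: list[DurationSummary], truth: list[DurationSummary]
) -> float:
    """Mean absolute error (minutes) over matching (identity, behavior) keys.

    Keys present on one side only raise, listing the missing keys — a
    silent partial mean would understate the error.
    """
    est = {(s.identity, s.behavior): s.minutes for s in estimated}
    tru = {(s.identity, s.behavior): s.minutes for s in truth}
    if est.keys() != tru.keys():
        missing = sorted(
            (k[0], k[1].value) for k in (est.keys() ^ tru.keys())
        )
        raise EvaluationError(f"duration key mismatch: {missing}")
    if not tru:
        raise EvaluationError("no duration keys to compare")
    return float(np.mean([abs(est[k] - tru[k]) for k in tru]))
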