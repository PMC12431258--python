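"""Evaluation: event-level endpoint accuracy and binary classification metrics.

Endpoint accuracy is precision-style: detected segments are matched
one-to-one to reference events greedily by interval IoU (threshold 0.3 by
default) and

    accuracy = 100 * f_r / f_a

where f_r is the number of correct detections and f_a the total number of
detections.  A companion recall (matched references / total references) is
reported as an extension since a pure precision figure hides misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amff_ed import SegmentList
from .errors import ValidationError

__all__ = ["DetectionEval", "ClassificationEval", "interval_iou",
           "endpoint_accuracy", "classification_metrics"]


@dataclass(frozen=True)
class DetectionEval:
    f_r: int  # correct detections
    f_a: int  # total detections
    accuracy_pct: float  # 100 * f_r / f_a (nan when f_a == 0)
    recall: float  # matched references / n_reference (extension)
    matching_iou: float
    n_reference: int
    missed: int


@dataclass(frozen=True)
class ClassificationEval:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TP, FN], [FP, TN]]
    positive_class: object


def interval_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 2) and (m, 2) half-open interval arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    inter = np.maximum(
        0.0,
        np.minimum(a[:, None, 1], b[None, :, 1])
        - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    union = (a[:, 1] - a[:, 0])[:, None] + (b[:, 1] - b[:, 0])[None, :] - inter
    return inter / np.where(union > 0, union, 1.0)


def endpoint_accuracy(
    detected: SegmentList, reference: SegmentList, iou_min: float = 0.3
) -> DetectionEval:
    """Match detections to reference events and compute endpoint accuracy.

    Matching is greedy by descending IoU, one-to-one, with IoU >= iou_min.
    With zero detections the accuracy ratio is undefined (reported as nan).
    """
    det, ref = detected.intervals(), reference.intervals()
    f_a, n_ref = det.shape[0], ref.shape[0]
    if f_a == 0:
        return DetectionEval(0, 0, float("nan"), 0.0 if n_ref else float("nan"),
                             iou_min, n_ref, n_ref)
    iou = interval_iou(det, ref)
    pairs = np.argwhere(iou >= iou_min)
    order = np.argsort(-iou[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_det, used_ref = set(), set()
    for d, r in pairs[order]:
        if d not in used_det and r not in used_ref:
            used_det.add(int(d))
            used_ref.add(int(r))
    f_r = len(used_det)
    return DetectionEval(
        f_r=f_r,
        f_a=f_a,
        accuracy_pct=100.0 * f_r / f_a,
        recall=(len(used_ref) / n_ref) if n_ref else float("nan"),
        matching_iou=iou_min,
        n_reference=n_ref,
        missed=n_ref - len(used_ref),
    )


def classification_metrics(predicted, truth, positive_class="osahs") -> ClassificationEval:
    """Confusion-matrix metrics for binary labels.

    Sensitivity is recall of the positive class (OSAHS by default);
    F1 is the harmonic mean of precision and sensitivity.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and true labels must have equal length")
    classes = set(np.unique(truth)) | set(np.unique(predicted))
    if len(classes) > 2:
        raise ValidationError(f"labels must be binary, got {sorted(map(str, classes))}")
    if positive_class not in classes:
        raise ValidationError(f"positive_class {positive_class!r} not among labels")

    pos_p = predicted == positive_class
    pos_t = truth == positive_class
    tp = int(np.sum(pos_p & pos_t))
    fn = int(np.sum(~pos_p & pos_t))
    fp = int(np.sum(pos_p & ~pos_t))
    tn = int(np.sum(~pos_p & ~pos_t))
    n = tp + fn + fp + tn

    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    return ClassificationEval(
        accuracy=(tp + tn) / n if n else float("nan"),
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        confusion=((tp, fn), (fp, tn)),
        positive_class=positive_class,
    )
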