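"""Evaluation protocol: IoU matching, detection and classification metrics.

Detection follows the standard object-detection accounting: a predicted box
is a true positive when its IoU with an unmatched ground-truth box reaches
the threshold (0.5 by default), matching greedily in descending confidence;
unmatched predictions are false positives and unmatched truth boxes false
negatives. Classification metrics are the usual confusion-matrix rates, the
full ROC curve with trapezoidal AUC, and an operating cut-off chosen by
maximizing Youden's J = TPR - FPR on a validation set. Metrics whose
denominator is zero are reported as absent (None), never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_io import BoundingBox3D
from .pipeline import Detection, iou, run_detection

__all__ = [
    "MatchResult",
    "ConfusionMatrix",
    "match_detections",
    "detection_metrics",
    "confusion_metrics",
    "confusion_from_rates",
    "roc_curve",
    "optimal_cutoff",
    "control_study",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tp_confidences: list[float] = field(default_factory=list)
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (det idx, truth idx)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def match_detections(
    detections: list[Detection],
    truth_boxes: list[BoundingBox3D],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-descending matching at the IoU threshold."""
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    matched_truth: set[int] = set()
    pairs, tp_conf = [], []
    fp = 0
    for di in order:
        det = detections[di]
        best_j, best_iou = -1, 0.0
        for j, tb in enumerate(truth_boxes):
            if j in matched_truth:
                continue
            v = iou(det.box, tb)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_truth.add(best_j)
            pairs.append((di, best_j))
            tp_conf.append(det.confidence)
        else:
            fp += 1
    return MatchResult(
        tp=len(pairs),
        fp=fp,
        fn=len(truth_boxes) - len(pairs),
        tp_confidences=tp_conf,
        pairs=pairs,
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def detection_metrics(match: MatchResult) -> dict:
    """Recall, precision, F1 and mean TP confidence from a MatchResult."""
    recall = _ratio(match.tp, match.tp + match.fn)
    precision = _ratio(match.tp, match.tp + match.fp)
    f1 = None
    if recall is not None and precision is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    mean_conf = float(np.mean(match.tp_confidences)) if match.tp_confidences else None
    return {
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "mean_tp_confidence": mean_conf,
    }


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV, FPR, F1 from counts."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    fpr = _ratio(cm.fp, cm.fp + cm.tn)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    f1 = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "fpr": fpr,
        "f1": f1,
    }


def confusion_from_rates(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> ConfusionMatrix:
    """Reconstruct integer counts implied by printed rates on a known split."""
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return ConfusionMatrix(tp=tp, fp=n_negative - tn, tn=tn, fn=n_positive - tp)


def roc_curve(labels, scores):
    """ROC points swept over the unique scores, plus trapezoidal AUC.

    Returns ``(points, auc)`` where points is a list of (fpr, tpr, threshold)
    ordered by increasing FPR, bracketed by the all-negative and all-positive
    operating points.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    points = []
    for t in thresholds:
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        points.append((float(fpr), float(tpr), float(t)))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def optimal_cutoff(roc_points) -> float:
    """Threshold maximizing Youden's J = TPR - FPR; ties favor sensitivity.

    Among thresholds achieving the maximal J, the lowest finite threshold is
    returned (classifying more cases positive, i.e. higher sensitivity).
    """
    best_j = -np.inf
    best_t = None
    for fpr, tpr, t in roc_points:
        if not np.isfinite(t):
            continue
        j = tpr - fpr
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t < best_t):
            best_j, best_t = j, t
    if best_t is None:  # only the inf point: degenerate, fall back to 0.5
        return 0.5
    return float(best_t)


def control_study(volumes, model, config=None) -> dict:
    """Run detection on filter-free volumes; a volume passes if no detection.

    Returns per-volume verdicts plus the pass fraction (the specificity of
    the presence/absence decision on a filter-free cohort).
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("control study needs at least one volume")
    verdicts = []
    for vol in volumes:
        dets = run_detection(vol, model, config)
        verdicts.append(len(dets) == 0)
    return {
        "verdicts": verdicts,
        "n_pass": sum(verdicts),
        "n_total": len(verdicts),
        "pass_fraction": sum(verdicts) / len(verdicts),
    }
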