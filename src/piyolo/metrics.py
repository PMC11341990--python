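"""Detection metrics: precision, recall, F1, AP and mAP.

Definitions follow the standard object-detection protocol: detections are
ranked by confidence and greedily matched to unmatched ground-truth boxes of
the same class at IoU >= ``iou_match``; precision P = TP/(TP+FP) and recall
R = TP/(TP+FN) trace the PR curve; AP is the area under the all-point
interpolated curve (precision envelope); mAP averages AP over the classes
present in the ground truth; F1 = 2PR/(P+R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "MetricsReport", "box_iou_matrix", "f1_from_counts",
    "precision_recall", "average_precision", "evaluate_map",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    ap: dict            # class id -> AP
    map: float
    n_classes: int


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (N,4) / (M,4) xyxy box arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    return p, r


def f1_from_counts(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def average_precision(tp_flags: np.ndarray, n_gt: int,
                      eleven_point: bool = False) -> float:
    """AP from score-ordered hit flags against ``n_gt`` ground-truth boxes.

    All-point interpolation integrates the precision envelope over recall;
    the classic 11-point alternative is available behind a flag.
    """
    if n_gt == 0:
        raise ValueError("AP undefined without ground-truth boxes")
    if tp_flags.size == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    if eleven_point:
        return float(np.mean([
            precision[recall >= t].max() if (recall >= t).any() else 0.0
            for t in np.linspace(0, 1, 11)
        ]))
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    p = np.maximum.accumulate(p[::-1])[::-1]          # precision envelope
    idx = np.nonzero(np.diff(r))[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def evaluate_map(preds: list, gts: list, iou_match: float = 0.5,
                 eleven_point: bool = False) -> MetricsReport:
    """Score detections against ground truth over a set of images.

    ``preds``: one DetectionSet (boxes/scores/classes) per image;
    ``gts``: matching list of LabeledImage-likes exposing pixel ``xyxy()``
    and ``class_ids()`` (or plain (boxes, classes) tuples).
    """
    def _gt_arrays(g):
        if hasattr(g, "xyxy"):
            return g.xyxy(), g.class_ids()
        return np.atleast_2d(np.asarray(g[0], dtype=float)), np.asarray(g[1])

    gt_boxes, gt_classes = zip(*[_gt_arrays(g) for g in gts]) if gts else ((), ())
    n_gt_total = sum(len(b) for b in gt_boxes)
    if n_gt_total == 0:
        raise ValueError("no ground-truth boxes: recall is undefined")

    classes_present = np.unique(np.concatenate(
        [c for c in gt_classes if len(c)] or [np.zeros(0, dtype=int)]))
    ap, total_tp, total_det = {}, 0, 0
    for cls in classes_present:
        rows = []  # (score, image index, det index)
        for i, ds in enumerate(preds):
            sel = np.nonzero(np.asarray(ds.classes) == cls)[0]
            rows += [(float(ds.scores[j]), i, j) for j in sel]
        # score-descending, ties stable by (image, detection index)
        rows.sort(key=lambda t: (-t[0], t[1], t[2]))
        n_gt = sum(int((gc == cls).sum()) for gc in gt_classes)
        matched = [np.zeros(len(b), dtype=bool) for b in gt_boxes]
        flags = np.zeros(len(rows), dtype=bool)
        for k, (_, i, j) in enumerate(rows):
            gb = gt_boxes[i]
            cand = np.nonzero((gt_classes[i] == cls) & ~matched[i])[0]
            if len(cand) == 0:
                continue
            box = np.asarray(preds[i].boxes[j], dtype=float)[None]
            ious = box_iou_matrix(box, gb[cand])[0]
            best = int(np.argmax(ious))
            if ious[best] >= iou_match:
                matched[i][cand[best]] = True
                flags[k] = True
        ap[int(cls)] = average_precision(flags, n_gt, eleven_point) if n_gt else 0.0
        total_tp += int(flags.sum())
        total_det += len(rows)

    counts = ConfusionCounts(TP=total_tp, FP=total_det - total_tp,
                             FN=n_gt_total - total_tp)
    p, r = precision_recall(counts)
    return MetricsReport(
        precision=p, recall=r, f1=f1_from_counts(p, r), ap=ap,
        map=float(np.mean(list(ap.values()))), n_classes=len(classes_present),
    )
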