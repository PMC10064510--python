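"""Detection and segmentation quality metrics.

Predictions are matched to ground-truth boxes greedily in descending
confidence order under an IoU criterion; from the resulting true/false
positive and false negative counts the standard detection metrics follow:

    precision = TP / (TP + FP)        (all detected stomata in the denominator)
    recall    = TP / (TP + FN)        (total number of stomata in the denominator)
    F1        = 2 * P * R / (P + R)   (harmonic mean)

A confidence curve sweeps the detector's score threshold over a grid and
reports the three metrics at each point, plus the F1-optimal threshold.
Mask-level agreement uses polygon intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .detection import DetectionBox
from .measure import StomaMask

__all__ = [
    "MatchResult",
    "DetectionMetrics",
    "ConfidenceCurve",
    "iou",
    "match_detections",
    "compute_metrics",
    "f1_score",
    "confidence_curve",
    "mask_agreement",
]

Box = tuple[float, float, float, float]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two half-open ``(x, y, w, h)`` boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Outcome of matching predictions to ground truth on one image."""

    pairs: list[tuple[int, int, float]]  # (gt_index, pred_index, IoU)
    false_positives: list[int]  # unmatched prediction indices
    false_negatives: list[int]  # unmatched ground-truth indices
    iou_threshold: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass
class ConfidenceCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    best_threshold: float


def match_detections(
    gt: list[Box] | list[DetectionBox],
    preds: list[DetectionBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching.

    Predictions are visited in descending confidence (ties broken by the
    higher best-available IoU, then input order); each claims the unmatched
    ground-truth box of highest IoU, accepted iff IoU >= ``iou_threshold``.
    Unclaimed predictions are false positives, unclaimed ground truth false
    negatives.
    """
    gt_boxes: list[Box] = [g.bbox if isinstance(g, DetectionBox) else tuple(g) for g in gt]
    iou_matrix = np.array(
        [[iou(p.bbox, g) for g in gt_boxes] for p in preds], dtype=float
    ).reshape(len(preds), len(gt_boxes))
    best_avail = iou_matrix.max(axis=1) if gt_boxes else np.zeros(len(preds))
    order = sorted(
        range(len(preds)),
        key=lambda i: (-preds[i].confidence, -best_avail[i], i),
    )
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    false_positives: list[int] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in range(len(gt_boxes)):
            if j in matched_gt:
                continue
            v = iou_matrix[i, j]
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_gt.add(best_j)
            pairs.append((best_j, i, float(best_iou)))
        else:
            false_positives.append(i)
    false_negatives = [j for j in range(len(gt_boxes)) if j not in matched_gt]
    return MatchResult(pairs, sorted(false_positives), false_negatives, iou_threshold)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(match: MatchResult) -> DetectionMetrics:
    """Precision, recall and F1 from a match result.

    With zero predictions precision is 1.0 (no false claims were made);
    with zero ground truth recall is 1.0.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return DetectionMetrics(precision, recall, f1_score(precision, recall), tp, fp, fn)


def confidence_curve(
    gt: list[Box] | list[DetectionBox],
    preds: list[DetectionBox],
    iou_threshold: float = 0.5,
    grid_size: int = 101,
) -> ConfidenceCurve:
    """Metrics as a function of the detection confidence threshold.

    At each threshold in an even grid over [0, 1], predictions below the
    threshold are discarded, matching is redone and metrics recomputed.
    ``best_threshold`` maximizes F1 (ties: lowest threshold).
    """
    thresholds = np.linspace(0.0, 1.0, grid_size)
    precision = np.empty(grid_size)
    recall = np.empty(grid_size)
    f1 = np.empty(grid_size)
    for k, thr in enumerate(thresholds):
        kept = [p for p in preds if p.confidence >= thr]
        m = compute_metrics(match_detections(gt, kept, iou_threshold))
        precision[k], recall[k], f1[k] = m.precision, m.recall, m.f1
    best_threshold = float(thresholds[int(np.argmax(f1))])
    return ConfidenceCurve(thresholds, precision, recall, f1, best_threshold)


def mask_agreement(mask_a: StomaMask, mask_b: StomaMask) -> tuple[float, float | None]:
    """Polygon IoU of two stoma masks: (complex IoU, aperture IoU or None).

    The aperture term is None when either mask lacks an aperture. Raises on
    invalid (self-intersecting) polygons.
    """
    def poly_iou(pa: np.ndarray, pb: np.ndarray) -> float:
        a, b = Polygon(pa), Polygon(pb)
        if not (a.is_valid and b.is_valid):
            raise ValueError("invalid polygon in mask_agreement")
        union = a.union(b).area
        return a.intersection(b).area / union if union > 0 else 0.0

    if mask_a.complex_polygon is None or mask_b.complex_polygon is None:
        raise ValueError("mask_agreement requires complex polygons on both masks")
    complex_iou = poly_iou(mask_a.complex_polygon, mask_b.complex_polygon)
    aperture_iou = None
    if mask_a.aperture_polygon is not None and mask_b.aperture_polygon is not None:
        aperture_iou = poly_iou(mask_a.aperture_polygon, mask_b.aperture_polygon)
    return complex_iou, aperture_iou
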