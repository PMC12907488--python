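"""Segmentation and detection metrics.

Mask metrics: Dice, Jaccard and the 95th-percentile Hausdorff distance
(HD95).  HD95 is computed on surface voxels (foreground voxels with at
least one background face-neighbour), pooling both directed
surface-to-surface distance sets before taking the percentile, in mm via
the grid spacing.

Detection metrics: greedy confidence-ordered matching, precision/recall,
average precision with all-point interpolation (precision envelope),
mAP50 and mAP50-95 (IoU thresholds 0.50:0.05:0.95).  Class AP is
undefined when the class has no ground-truth instance and such classes
are excluded from the unweighted aggregate mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from ventriseg.subregions import N_CLASSES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mask metrics

@dataclass(frozen=True)
class SegScore:
    """Overlap and boundary scores for one mask pair."""

    dice: float
    jaccard: float
    hd95: float | None  # None when either mask is empty


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Both masks empty scores 1.0 by convention (correct absence), with a
    log record so the convention is visible in batch reports.
    """
    a, b = _check_shapes(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.info("dice: both masks empty, scoring 1.0 by convention")
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| (1.0 when both masks are empty)."""
    a, b = _check_shapes(a, b)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        log.info("jaccard: both masks empty, scoring 1.0 by convention")
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n, ndim) of foreground voxels with a background face-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    structure = generate_binary_structure(mask.ndim, 1)
    interior = binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff95(a: np.ndarray, b: np.ndarray,
                spacing: float | tuple[float, ...] = 1.0) -> float | None:
    """95th percentile of the pooled bidirectional surface distances in mm.

    Returns None (missing) when either mask is empty.
    """
    a, b = _check_shapes(a, b)
    if not a.any() or not b.any():
        return None
    sp = np.broadcast_to(np.atleast_1d(np.asarray(spacing, float)), (a.ndim,))
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def score_masks(a: np.ndarray, b: np.ndarray,
                spacing: float | tuple[float, ...] = 1.0) -> SegScore:
    return SegScore(dice=dice(a, b), jaccard=jaccard(a, b),
                    hd95=hausdorff95(a, b, spacing))


# ---------------------------------------------------------------------------
# detection metrics

def box_iou(a, b) -> float:
    """IoU of two normalized (cx, cy, w, h) boxes."""
    ax0, ay0, ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0, bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def _det_key(d):
    """Group detections by (slice, class)."""
    return (d.z_index, d.class_id)


def match_detections(gt_boxes, pred_boxes, iou_thresh: float):
    """Greedy TP/FP assignment of predictions to ground truth.

    Predictions are visited in descending confidence; each becomes a TP
    if its IoU with an unmatched same-class ground-truth box on the same
    slice reaches ``iou_thresh``.  Each ground-truth box is matched at
    most once.

    Returns (matches, n_gt): ``matches`` is a list of (detection,
    is_tp) in descending confidence order.
    """
    gt_pool: dict[tuple, list] = {}
    for g in gt_boxes:
        gt_pool.setdefault(_det_key(g), []).append([g, False])
    order = sorted(pred_boxes,
                   key=lambda d: (-d.confidence, d.class_id, d.z_index, d.cx, d.cy))
    matches = []
    for p in order:
        best_iou, best = iou_thresh, None
        for entry in gt_pool.get(_det_key(p), ()):
            if entry[1]:
                continue
            i = box_iou((p.cx, p.cy, p.w, p.h), (entry[0].cx, entry[0].cy, entry[0].w, entry[0].h))
            if i >= best_iou:
                best_iou, best = i, entry
        if best is not None:
            best[1] = True
            matches.append((p, True))
        else:
            matches.append((p, False))
    return matches, len(list(gt_boxes))


def average_precision(tp_flags, n_gt: int) -> float:
    """AP from confidence-sorted TP flags via the precision envelope.

    Area under the precision-recall curve with all-point interpolation:
    precision is replaced by its running maximum from the right and
    integrated over the recall steps.
    """
    if n_gt == 0:
        raise ValueError("AP undefined with no ground-truth instances")
    flags = np.asarray(list(tp_flags), dtype=float)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(1.0 - flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # envelope + step integration over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum(np.diff(mrec) * mpre[1:]))


@dataclass
class DetScore:
    """Per-class and aggregate detection scores at fixed IoU plus mAP50-95."""

    per_class: dict = field(default_factory=dict)
    precision: float = 0.0
    recall: float = 0.0
    ap50: float = 0.0
    ap50_95: float = 0.0
    n_gt: dict = field(default_factory=dict)


def _class_subset(boxes, class_id):
    return [b for b in boxes if b.class_id == class_id]


def _class_ap(gt, pred, iou_thresh):
    matches, n_gt = match_detections(gt, pred, iou_thresh)
    if n_gt == 0:
        return None
    return average_precision([tp for _, tp in matches], n_gt)


def detection_scores(gt_boxes, pred_boxes, iou_thresh: float = 0.5) -> DetScore:
    """Precision, recall, AP50 and mAP50-95 per class and aggregated.

    The aggregate is the unweighted mean over classes with at least one
    ground-truth instance.
    """
    thresholds = np.arange(0.5, 0.96, 0.05)
    score = DetScore()
    agg = {"precision": [], "recall": [], "ap50": [], "ap50_95": []}
    for cid in range(N_CLASSES):
        gt_c = _class_subset(gt_boxes, cid)
        pred_c = _class_subset(pred_boxes, cid)
        score.n_gt[cid] = len(gt_c)
        if not gt_c:
            continue
        matches, n_gt = match_detections(gt_c, pred_c, iou_thresh)
        tp = sum(1 for _, is_tp in matches if is_tp)
        prec = tp / len(matches) if matches else 0.0
        rec = tp / n_gt
        ap50 = _class_ap(gt_c, pred_c, 0.5)
        aps = [_class_ap(gt_c, pred_c, t) for t in thresholds]
        ap50_95 = float(np.mean(aps))
        score.per_class[cid] = {"precision": prec, "recall": rec,
                                "ap50": ap50, "ap50_95": ap50_95}
        for k, v in zip(agg, (prec, rec, ap50, ap50_95)):
            agg[k].append(v)
    if agg["ap50"]:
        score.precision = float(np.mean(agg["precision"]))
        score.recall = float(np.mean(agg["recall"]))
        score.ap50 = float(np.mean(agg["ap50"]))
        score.ap50_95 = float(np.mean(agg["ap50_95"]))
    return score


def map50_95(gt_boxes, pred_boxes) -> float:
    """Mean AP over IoU thresholds 0.50 to 0.95 in steps of 0.05."""
    return detection_scores(gt_boxes, pred_boxes).ap50_95
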