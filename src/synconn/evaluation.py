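"""Instance-level detection scoring.

Predicted and ground-truth instance labelings are matched one-to-one:
candidate pairs with IoU >= ``min_iou`` are sorted by descending overlap
(ties: lower predicted id, then lower ground-truth id) and accepted
greedily. Precision = TP/(TP+FP), recall = TP/(TP+FN); an empty denominator
scores 1.0. A voxel-level Dice coefficient is offered as an auxiliary
output; an optional evaluation region restricts both labelings before
matching (scoring only where ground truth exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BinaryMask, LabelVolume

__all__ = ["Match", "DetectionMetrics", "match_instances", "precision_recall",
           "evaluate_detection", "voxel_dice"]


@dataclass(frozen=True)
class Match:
    pred_id: int
    gt_id: int
    overlap_voxels: int
    iou: float


@dataclass
class DetectionMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    matches: list[Match] = field(default_factory=list)


def _apply_region(lab: np.ndarray, region: BinaryMask | None) -> np.ndarray:
    if region is None:
        return lab
    if region.data.shape != lab.shape:
        raise ValueError(f"region shape {region.data.shape} != labels shape {lab.shape}")
    out = lab.copy()
    out[~region.data] = 0
    return out


def match_instances(pred: LabelVolume, gt: LabelVolume, min_iou: float = 0.1,
                    region: BinaryMask | None = None) -> list[Match]:
    """Greedy one-to-one matching of predicted to ground-truth instances."""
    if pred.data.shape != gt.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {gt.data.shape}")
    p = _apply_region(pred.data, region)
    g = _apply_region(gt.data, region)
    p_counts = np.bincount(p.ravel())
    g_counts = np.bincount(g.ravel())
    both = (p > 0) & (g > 0)
    if not both.any():
        return []
    pv = p[both].astype(np.int64)
    gv = g[both].astype(np.int64)
    base = int(g.max()) + 1
    key = pv * base + gv
    uniq, counts = np.unique(key, return_counts=True)
    cands = []
    for k, ov in zip(uniq, counts):
        pid, gid = int(k // base), int(k % base)
        union = p_counts[pid] + g_counts[gid] - ov
        iou = ov / union
        if iou >= min_iou:
            cands.append((int(ov), pid, gid, float(iou)))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    matches: list[Match] = []
    for ov, pid, gid, iou in cands:
        if pid in used_p or gid in used_g:
            continue
        used_p.add(pid)
        used_g.add(gid)
        matches.append(Match(pred_id=pid, gt_id=gid, overlap_voxels=ov, iou=iou))
    return matches


def precision_recall(matches: list[Match], n_pred: int, n_gt: int) -> DetectionMetrics:
    """Confusion counts and rates from a one-to-one match table."""
    tp = len(matches)
    fp = n_pred - tp
    fn = n_gt - tp
    if fp < 0 or fn < 0:
        raise ValueError(
            f"match count {tp} exceeds n_pred={n_pred} or n_gt={n_gt}: inconsistent inputs")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return DetectionMetrics(true_positives=tp, false_positives=fp, false_negatives=fn,
                            precision=precision, recall=recall, matches=matches)


def _n_instances(lab: np.ndarray, region: BinaryMask | None) -> int:
    l = _apply_region(lab, region)
    return int(len(np.unique(l[l > 0])))


def evaluate_detection(pred: LabelVolume, gt: LabelVolume, min_iou: float = 0.1,
                       region: BinaryMask | None = None) -> DetectionMetrics:
    """match_instances + precision_recall in one call."""
    matches = match_instances(pred, gt, min_iou, region)
    return precision_recall(matches, _n_instances(pred.data, region),
                            _n_instances(gt.data, region))


def voxel_dice(pred: LabelVolume, gt: LabelVolume, region: BinaryMask | None = None) -> float:
    """Auxiliary voxel-level Dice coefficient of the foregrounds (1.0 if both empty)."""
    p = _apply_region(pred.data, region) > 0
    g = _apply_region(gt.data, region) > 0
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom
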