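"""Instance-level segmentation evaluation: sweeping IoU and F1/AP.

The primary accuracy readout is the *retained fraction*: the proportion of
ground-truth nuclei whose one-to-one matched prediction reaches IoU >= t,
plotted for t swept from 0.55 (least stringent) to 0.80 (most stringent).
Unlike pixel accuracy, IoU is insensitive to class imbalance and penalizes
masks of the wrong size or shape, which matters when masks are used to
quantify marker intensities.

Matching is a globally optimal one-to-one assignment on the IoU matrix
(pairs below the threshold are never matched).  At the conventional 50%
overlap cutoff the matched/unmatched counts give TP/FP/FN, from which
precision (TP normalized to predictions), recall (TP normalized to ground
truth), their harmonic mean F1, and AP = TP/(TP+FP+FN) are derived.
The same operations support scoring one annotator against another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy import sparse

__all__ = [
    "DEFAULT_THRESHOLDS",
    "MatchResult",
    "IoUCurve",
    "InstanceScores",
    "mask_iou",
    "pairwise_iou",
    "match_instances",
    "retained_fraction_curve",
    "instance_scores",
    "annotator_agreement",
]

#: IoU sweep grid, least to most stringent.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.55, 0.60, 0.65, 0.70, 0.75, 0.80)


@dataclass
class MatchResult:
    """One-to-one matching between two instance maps at an IoU cutoff."""

    pairs: list[tuple[int, int, float]]
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    threshold: float

    @property
    def total_iou(self) -> float:
        return float(sum(iou for _, _, iou in self.pairs))


@dataclass
class IoUCurve:
    """Retained fraction of ground-truth instances vs IoU threshold."""

    thresholds: np.ndarray
    retained_fraction: np.ndarray

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - t)))
        if abs(self.thresholds[i] - t) > 1e-9:
            raise KeyError(f"threshold {t} not on the grid {self.thresholds}")
        return float(self.retained_fraction[i])


@dataclass
class InstanceScores:
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    ap: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn = self.tp, self.fp, self.fn
        self.precision = tp / (tp + fp) if tp + fp else 0.0
        self.recall = tp / (tp + fn) if tp + fn else 0.0
        denom = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / denom if denom else 0.0
        self.ap = tp / (tp + fp + fn) if tp + fp + fn else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU (Jaccard index) of two boolean masks: |a & b| / |a | b|."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    if not a.any() or not b.any():
        raise ValueError("mask_iou requires non-empty masks")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union)


def pairwise_iou(
    gt: np.ndarray, pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IoU matrix between all gt/pred instance pairs with any overlap.

    Returns ``(gt_ids, pred_ids, iou)`` where ``iou[i, j]`` is the IoU of
    ``gt_ids[i]`` with ``pred_ids[j]`` (0 where they do not overlap).
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("instance maps must share a shape")
    gt_ids = np.unique(gt[gt > 0])
    pred_ids = np.unique(pred[pred > 0])
    if len(gt_ids) == 0 or len(pred_ids) == 0:
        return gt_ids, pred_ids, np.zeros((len(gt_ids), len(pred_ids)))
    gi = np.searchsorted(gt_ids, gt.ravel())
    pi = np.searchsorted(pred_ids, pred.ravel())
    both = (gt.ravel() > 0) & (pred.ravel() > 0)
    inter = sparse.coo_matrix(
        (np.ones(both.sum()), (gi[both], pi[both])),
        shape=(len(gt_ids), len(pred_ids)),
    ).toarray()
    areas_gt = np.array([(gt == g).sum() for g in gt_ids], dtype=float)
    areas_pr = np.array([(pred == p).sum() for p in pred_ids], dtype=float)
    union = areas_gt[:, None] + areas_pr[None, :] - inter
    return gt_ids, pred_ids, inter / union


def match_instances(
    gt: np.ndarray, pred: np.ndarray, iou_threshold: float
) -> MatchResult:
    """Optimal one-to-one matching maximizing total IoU at a cutoff.

    Only pairs with IoU >= ``iou_threshold`` are eligible.  The assignment
    maximizes the summed IoU over matched pairs; equal-value ties resolve
    toward lower (gt, pred) ids.
    """
    gt_ids, pred_ids, iou = pairwise_iou(gt, pred)
    pairs: list[tuple[int, int, float]] = []
    if iou.size:
        eligible = iou >= iou_threshold
        score = np.where(eligible, iou, 0.0)
        # infinitesimal preference for lower ids on exact ties
        eps = 1e-12
        ii, jj = np.mgrid[0 : iou.shape[0], 0 : iou.shape[1]]
        score = score + eps * (2.0 - ii / (iou.shape[0] + 1.0) - jj / (iou.shape[1] + 1.0)) * eligible
        rows, cols = linear_sum_assignment(-score)
        for i, j in zip(rows, cols):
            if eligible[i, j]:
                pairs.append((int(gt_ids[i]), int(pred_ids[j]), float(iou[i, j])))
    matched_gt = {g for g, _, _ in pairs}
    matched_pr = {p for _, p, _ in pairs}
    return MatchResult(
        pairs=sorted(pairs),
        unmatched_gt=[int(g) for g in gt_ids if g not in matched_gt],
        unmatched_pred=[int(p) for p in pred_ids if p not in matched_pr],
        threshold=float(iou_threshold),
    )


def retained_fraction_curve(
    gt: np.ndarray,
    pred: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> IoUCurve:
    """Sweeping-IoU curve: fraction of gt instances matched at >= t.

    Matching is recomputed at every threshold.  Requires at least one
    ground-truth instance.
    """
    gt = np.asarray(gt)
    n_gt = len(np.unique(gt[gt > 0]))
    if n_gt == 0:
        raise ValueError("retained_fraction_curve requires >= 1 gt instance")
    thresholds = np.asarray(thresholds, dtype=float)
    fracs = np.empty_like(thresholds)
    for k, t in enumerate(thresholds):
        fracs[k] = len(match_instances(gt, pred, t).pairs) / n_gt
    return IoUCurve(thresholds=thresholds, retained_fraction=fracs)


def instance_scores(
    gt: np.ndarray, pred: np.ndarray, overlap_threshold: float = 0.5
) -> InstanceScores:
    """TP/FP/FN and derived scores at the conventional 50% overlap."""
    m = match_instances(gt, pred, overlap_threshold)
    return InstanceScores(
        tp=len(m.pairs), fp=len(m.unmatched_pred), fn=len(m.unmatched_gt)
    )


def annotator_agreement(
    ann_a: np.ndarray, ann_b: np.ndarray
) -> tuple[InstanceScores, IoUCurve]:
    """Score one annotation set against another (``ann_a`` as reference)."""
    return (
        instance_scores(ann_a, ann_b, 0.5),
        retained_fraction_curve(ann_a, ann_b),
    )
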