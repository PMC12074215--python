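"""Rotated-box detection evaluation and count-regression metrics.

Detections are matched to ground truth greedily in descending score order
using the exact polygon IoU; average precision integrates the all-point
interpolated precision envelope over recall; mAP50 evaluates at IoU 0.5 and
mAP50-95 averages over thresholds 0.50:0.05:0.95.  Counting quality of a
detector used as a per-image counter is summarized by R^2, MAE, RMSE and
MAPE against manual counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from oeyolo.geometry import Detection, OrientedBox, polygon_iou

__all__ = [
    "MatchResult",
    "CountStats",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "counting_metrics",
]


@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP/FP flags (score-ordered) and the FN count."""

    scores: np.ndarray  # descending
    is_tp: np.ndarray  # bool, aligned with scores
    class_ids: np.ndarray
    n_gt: int
    fn: int
    iou_threshold: float

    @property
    def tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def fp(self) -> int:
        return int((~self.is_tp).sum())


@dataclass(frozen=True)
class CountStats:
    """Count-regression quality: R^2, MAE, RMSE, MAPE (percent)."""

    r2: float
    mae: float
    rmse: float
    mape: float


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[OrientedBox],
    iou_thr: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    Each detection claims its highest-IoU still-unmatched ground truth if
    that IoU reaches the threshold (TP), else it is a false positive;
    unmatched ground truths are false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    matched = [False] * len(gts)
    scores = np.array([dets[i].score for i in order], dtype=float)
    class_ids = np.array([dets[i].class_id for i in order], dtype=int)
    is_tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            iou = polygon_iou(dets[i].box, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            is_tp[rank] = True
    fn = matched.count(False)
    return MatchResult(scores, is_tp, class_ids, len(gts), fn, iou_thr)


def precision_recall(m: MatchResult) -> Tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); degenerate conventions P := 1 with no
    detections and R := 1 with no ground truths."""
    tp, fp = m.tp, m.fp
    p = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    r = 1.0 if m.n_gt == 0 else tp / m.n_gt
    return p, r


def average_precision(
    scored_flags: Sequence[Tuple[float, bool]], n_gt: int
) -> float:
    """All-point interpolated average precision.

    ``scored_flags`` pools (score, is_tp) over images; detections are sorted
    by descending score, the precision envelope (max precision at any recall
    >= r) is integrated over the distinct recall steps.  Returns NaN when
    there is nothing to evaluate (no ground truth and no detections).
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0:
        return math.nan if not scored_flags else 0.0
    if not scored_flags:
        return 0.0
    order = sorted(range(len(scored_flags)), key=lambda i: -scored_flags[i][0])
    flags = np.array([bool(scored_flags[i][1]) for i in order])
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # envelope: precision at recall r is the max precision at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    # sum over recall steps
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_ap(
    dets_per_image: Sequence[Sequence[Detection]],
    gts_per_image: Sequence[Sequence[OrientedBox]],
    thresholds: Optional[Sequence[float]] = None,
) -> Tuple[float, float, Dict[float, float]]:
    """(mAP50, mAP50-95, per-threshold AP) over a dataset.

    AP at each threshold pools scored TP/FP flags over all images (single
    class; with multiple classes the per-class APs are macro-averaged).
    """
    if thresholds is None:
        thresholds = [0.5 + 0.05 * i for i in range(10)]
    classes = sorted(
        {d.class_id for dets in dets_per_image for d in dets}
        | {0} if gts_per_image else {0}
    )
    per_thr: Dict[float, float] = {}
    for thr in thresholds:
        aps = []
        for cls in classes:
            flags: List[Tuple[float, bool]] = []
            n_gt = 0
            for dets, gts in zip(dets_per_image, gts_per_image):
                cls_dets = [d for d in dets if d.class_id == cls]
                m = match_detections(cls_dets, gts, thr)
                flags.extend(zip(m.scores.tolist(), m.is_tp.tolist()))
                n_gt += len(gts)
            ap = average_precision(flags, n_gt)
            if not math.isnan(ap):
                aps.append(ap)
        per_thr[float(thr)] = float(np.mean(aps)) if aps else math.nan
    map50 = per_thr.get(0.5, math.nan)
    in_range = [v for k, v in per_thr.items() if 0.5 - 1e-9 <= k <= 0.95 + 1e-9]
    map5095 = float(np.mean(in_range)) if in_range else math.nan
    return map50, map5095, per_thr


def counting_metrics(
    pred_counts: Sequence[int], gt_counts: Sequence[int]
) -> CountStats:
    """Per-image count regression metrics against manual counts.

    MAE = mean |p - g|; RMSE = sqrt(mean (p - g)^2);
    MAPE = 100 * mean(|p - g| / g) (any g = 0 is an error);
    R^2 = 1 - SS_res / SS_tot about the mean of g.
    """
    p = np.asarray(pred_counts, dtype=float)
    g = np.asarray(gt_counts, dtype=float)
    if p.shape != g.shape or p.size == 0:
        raise ValueError("pred and gt counts must be equal-length and nonempty")
    if np.any(g == 0):
        raise ValueError("MAPE undefined: a ground-truth count is zero")
    err = p - g
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(100.0 * np.mean(np.abs(err) / g))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return CountStats(r2=r2, mae=mae, rmse=rmse, mape=mape)
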