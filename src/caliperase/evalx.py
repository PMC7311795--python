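"""Detection evaluation: IoU matching, precision/recall/F-score, interpolated AP.

Definitions used throughout:

* ``P = TP / (TP + FP)``, ``R = TP / (TP + FN)``, ``F = 2PR / (P + R)``;
* ``AP = ∫_0^1 P(R0) dR0`` where ``P(R0)`` is the maximum precision at any
  recall ≥ R0 (all-point interpolation, evaluated as an exact
  piecewise-constant sum over the score-ranked detections);
* ``mAP`` is the mean AP over classes — a single class ("nodule") here.

Matching is greedy, score-ordered and one-to-one: each detection, in
descending score order, claims the unmatched ground-truth box of highest
IoU ≥ threshold (TP) or counts as a false positive; unclaimed ground truths
are false negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

Box = tuple[float, float, float, float]


class ContractError(ValueError):
    pass


@dataclass
class MatchCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0  # unused in detection mode, kept for completeness

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.TP += other.TP
        self.FP += other.FP
        self.FN += other.FN
        self.TN += other.TN
        return self


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ContractError("degenerate (zero-area) box")
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def _box_score(det) -> tuple[Box, float]:
    if hasattr(det, "bbox"):
        return tuple(det.bbox), float(det.score)
    box, score = det
    return tuple(box), float(score)


def _sorted_dets(dets) -> list[tuple[Box, float]]:
    pairs = [_box_score(d) for d in dets]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def match_detections(dets, gts: list[Box], iou_thresh: float
                     ) -> tuple[MatchCounts, list[bool]]:
    """Greedy one-to-one matching; returns counts and a per-detection TP flag.

    ``dets`` may be ``(bbox, score)`` pairs or objects with ``.bbox`` /
    ``.score``; they are sorted by descending score internally (ties broken
    by box coordinates for determinism). TP flags follow that sorted order.
    """
    pairs = _sorted_dets(dets)
    matched = [False] * len(gts)
    flags: list[bool] = []
    tp = fp = 0
    for box, _score in pairs:
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(box, gt)
            if v >= iou_thresh and v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
            flags.append(True)
        else:
            fp += 1
            flags.append(False)
    fn = matched.count(False)
    return MatchCounts(TP=tp, FP=fp, FN=fn), flags


def precision_recall_f(c: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and F-score from match counts.

    F is defined as 0 when P + R = 0. If both denominators are zero (no
    detections and no ground truth) the metrics are undefined and NaN is
    returned with a warning.
    """
    if c.TP + c.FP == 0 and c.TP + c.FN == 0:
        warnings.warn("precision and recall undefined: no detections and no ground truth")
        return (float("nan"),) * 3
    p = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else 0.0
    r = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


def _pooled_flags(dets_by_image: dict, gts_by_image: dict, iou_thresh: float
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool per-image TP flags across the dataset, ranked by descending score."""
    rows = []  # (score, tiebreak, is_tp)
    n_gt = 0
    for key in sorted(gts_by_image):
        gts = gts_by_image[key]
        n_gt += len(gts)
        dets = dets_by_image.get(key, [])
        pairs = _sorted_dets(dets)
        _, flags = match_detections(pairs, gts, iou_thresh)
        for (box, score), tp in zip(pairs, flags):
            rows.append((score, (key, box), tp))
    rows.sort(key=lambda r: (-r[0], r[1]))
    scores = np.array([r[0] for r in rows], dtype=float)
    flags = np.array([r[2] for r in rows], dtype=bool)
    return scores, flags, n_gt


def _normalize(dets, gts):
    """Accept flat single-image lists or per-image dicts."""
    if isinstance(gts, dict):
        return dets, gts
    return {0: list(dets)}, {0: list(gts)}


def average_precision(dets, gts, iou_thresh: float = 0.3) -> float:
    """All-point interpolated average precision for the single nodule class.

    ``dets``/``gts`` may be flat lists (single image) or dicts keyed by
    image id. Raises :class:`ContractError` when there is no ground truth.
    """
    dets_by_image, gts_by_image = _normalize(dets, gts)
    _, flags, n_gt = _pooled_flags(dets_by_image, gts_by_image, iou_thresh)
    if n_gt == 0:
        raise ContractError("average precision undefined without ground truth")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / n_gt
    # interpolate: P(R0) = max precision at recall >= R0
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(p_interp, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_average_precision(dets, gts, iou_thresh: float = 0.3) -> float:
    """mAP = mean of per-class AP; a single class here, so mAP = AP."""
    return average_precision(dets, gts, iou_thresh)


def best_f_operating_point(dets, gts, iou_thresh: float = 0.3
                           ) -> tuple[float, float, float]:
    """(precision, recall, F) at the score threshold maximizing F.

    Scans every cut of the pooled score ranking and returns the F-optimal
    point; used for the recall/F columns of the condition-grid report.
    """
    dets_by_image, gts_by_image = _normalize(dets, gts)
    _, flags, n_gt = _pooled_flags(dets_by_image, gts_by_image, iou_thresh)
    if n_gt == 0:
        raise ContractError("recall undefined without ground truth")
    best = (0.0, 0.0, 0.0)
    tp = 0
    for k, is_tp in enumerate(flags, start=1):
        tp += int(is_tp)
        p = tp / k
        r = tp / n_gt
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        if f > best[2]:
            best = (p, r, f)
    return best


def evaluate_detections(dets_by_image: dict, gts_by_image: dict,
                        iou_thresholds: tuple[float, ...] = (0.4, 0.3)) -> dict:
    """Per-threshold mAP / recall / F-score summary (fractions in [0, 1])."""
    out = {}
    for t in iou_thresholds:
        ap = average_precision(dets_by_image, gts_by_image, t)
        p, r, f = best_f_operating_point(dets_by_image, gts_by_image, t)
        out[t] = {"mAP": ap, "precision": p, "recall": r, "fscore": f}
    return out
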