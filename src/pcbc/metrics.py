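"""Detection matching, precision-recall analysis and classification error.

A detection matches a ground-truth object when its decoded position (and
scale, when both carry one) is sufficiently close.  Matching is greedy in
descending score order; each truth can be matched at most once, and any
further detection close to an already-matched truth counts as a false
positive.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "MatchResult", "PRPoint", "match_detections", "pr_curve", "f_score",
    "equal_error_rate", "classification_error",
]


@dataclasses.dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list


@dataclasses.dataclass
class PRPoint:
    threshold: float
    recall: float
    precision: float
    tp: int
    fp: int
    fn: int


def _close(det, truth, pos_tolerance, scale_tolerance) -> bool:
    if pos_tolerance is None:
        tol = 0.25 * float(getattr(truth, "width", 0.0))
        if tol <= 0:
            raise ValueError(
                "pos_tolerance=None requires truths with a positive width")
    else:
        tol = float(pos_tolerance)
    dr = det.row - truth.row
    dc = det.col - truth.col
    if np.hypot(dr, dc) > tol:
        return False
    det_scale = getattr(det, "scale", None)
    truth_scale = getattr(truth, "scale", None)
    if det_scale is not None and truth_scale not in (None, 0):
        if abs(det_scale / truth_scale - 1.0) > scale_tolerance:
            return False
    return True


def match_detections(dets: Sequence, truths: Sequence,
                     pos_tolerance: float | None = None,
                     scale_tolerance: float = 0.25) -> MatchResult:
    """Match one image's detections to its ground truth.

    Detections are processed in descending score order.  A detection
    close to an unmatched truth is a true positive (nearest such truth is
    taken); one close only to already-matched truths, or close to none,
    is a false positive.  Unmatched truths are false negatives.

    ``pos_tolerance`` is the maximum centre distance in pixels (default:
    25 % of each truth's width); ``scale_tolerance`` the maximum relative
    scale mismatch.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(truths)
    pairs = []
    tp = fp = 0
    for i in order:
        det = dets[i]
        close = [j for j, t in enumerate(truths)
                 if _close(det, t, pos_tolerance, scale_tolerance)]
        free = [j for j in close if not matched[j]]
        if free:
            j = min(free, key=lambda j: np.hypot(det.row - truths[j].row,
                                                 det.col - truths[j].col))
            matched[j] = True
            pairs.append((det, truths[j]))
            tp += 1
        else:
            fp += 1
    fn = len(truths) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def pr_curve(samples: Sequence, thresholds: Sequence[float] | None = None,
             pos_tolerance: float | None = None,
             scale_tolerance: float = 0.25) -> list[PRPoint]:
    """Pooled precision-recall curve over a threshold sweep.

    ``samples`` holds ``(detections, truths)`` pairs, one per image.  At
    each threshold, detections scoring at least the threshold are matched
    per image and the counts pooled.  Precision with no detections is
    reported as 1.  The default sweep spans all-accept (threshold 0) to
    all-reject (just above the top score).
    """
    samples = list(samples)
    total_truths = sum(len(truths) for _, truths in samples)
    if total_truths == 0:
        raise ValueError("no ground-truth objects in any image")
    if thresholds is None:
        scores = sorted({float(d.score) for dets, _ in samples for d in dets})
        if scores:
            thresholds = [0.0] + scores + [scores[-1] + 1.0]
        else:
            thresholds = [0.0, 1.0]
    curve = []
    for t in thresholds:
        tp = fp = fn = 0
        for dets, truths in samples:
            kept = [d for d in dets if d.score >= t]
            res = match_detections(kept, truths, pos_tolerance,
                                   scale_tolerance)
            tp += res.tp
            fp += res.fp
            fn += res.fn
        recall = tp / (tp + fn)
        precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
        curve.append(PRPoint(threshold=float(t), recall=recall,
                             precision=precision, tp=tp, fp=fp, fn=fn))
    return curve


def f_score(tp: int, fp: int, fn: int) -> float:
    """``2 TP / (2 TP + FP + FN)``, the harmonic mean of precision and recall."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("f score undefined for all-zero counts")
    return 2.0 * tp / (2.0 * tp + fp + fn)


def equal_error_rate(curve: Sequence[PRPoint]) -> float:
    """Percent error at the threshold where false positives equal false negatives.

    When no curve point has FP == FN exactly, the counts are linearly
    interpolated between the bracketing thresholds.  Returned as
    ``100 * FN / (TP + FN)`` at the crossing.
    """
    curve = list(curve)
    if len(curve) < 2:
        raise ValueError("curve must span at least two thresholds")
    pts = sorted(curve, key=lambda p: p.threshold)
    total = pts[0].tp + pts[0].fn
    diffs = [p.fp - p.fn for p in pts]
    for i, p in enumerate(pts):
        if diffs[i] == 0:
            return 100.0 * p.fn / (p.tp + p.fn)
    for i in range(len(pts) - 1):
        if diffs[i] > 0 > diffs[i + 1]:
            alpha = diffs[i] / (diffs[i] - diffs[i + 1])
            fn_star = pts[i].fn + alpha * (pts[i + 1].fn - pts[i].fn)
            return 100.0 * fn_star / total
    # No crossing: report the error at the point of closest FP/FN balance.
    best = min(pts, key=lambda p: abs(p.fp - p.fn))
    return 100.0 * best.fn / (best.tp + best.fn)


def classification_error(predictions: Sequence, labels: Sequence) -> float:
    """Percent of mismatching prediction/label pairs."""
    predictions = list(predictions)
    labels = list(labels)
    if not predictions or len(predictions) != len(labels):
        raise ValueError("predictions and labels must be equal-length and "
                         "non-empty")
    wrong = sum(1 for p, t in zip(predictions, labels) if p != t)
    return 100.0 * wrong / len(labels)
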