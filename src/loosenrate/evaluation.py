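"""Detection and bunch-classification metrics.

Two layers of evaluation live here:

* standard detection metrics — greedy IoU matching, precision, recall, F1,
  per-class average precision (all-point interpolation) and their mean
  (mAP);
* bunch-level classification — tallying qualified/unqualified verdicts
  into a confusion matrix and sweeping the detection-confidence threshold
  to find the F1-maximizing operating point.

Convention throughout: the *positive* class is an **unqualified** bunch
(the defect the system exists to catch), which inverts the intuitive
"positive = good".  A detected bunch with no ground-truth match carries an
implicit qualified truth; a missed ground-truth bunch carries an implicit
qualified prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import Box, iou
from .loosening import (
    BunchAssessment,
    Detection,
    LooseningConfig,
    ObjectClass,
    assess_scene,
)

__all__ = [
    "ConfusionCounts",
    "SweepRow",
    "PRCurve",
    "precision",
    "recall",
    "f1",
    "accuracy_breakdown",
    "match_detections",
    "tally_bunches",
    "average_precision",
    "pr_curve",
    "mean_ap",
    "confidence_sweep",
    "sweep_from_counts",
    "best_threshold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Bunch-level confusion matrix; positive class = unqualified bunch."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when no positive predictions exist."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when no actual positives exist."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    p, r = precision(counts), recall(counts)
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def accuracy_breakdown(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(overall, predicted-unqualified, predicted-qualified) accuracies.

    Overall is (TP+TN)/total; the per-predicted-class accuracies are
    TP/(TP+FP) for bunches predicted unqualified and TN/(TN+FN) for bunches
    predicted qualified.  Zero denominators yield 0.
    """
    overall = (counts.tp + counts.tn) / counts.total if counts.total else 0.0
    unq = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0
    q = counts.tn / (counts.tn + counts.fn) if (counts.tn + counts.fn) else 0.0
    return overall, unq, q


@dataclass(frozen=True)
class SweepRow:
    """One confidence threshold's tally and metrics in a sweep table."""

    conf_threshold: float
    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, threshold: float, counts: ConfusionCounts) -> "SweepRow":
        return cls(threshold, counts, precision(counts), recall(counts), f1(counts))


def match_detections(
    dets: Sequence[Detection],
    ground_truth: Sequence[Box],
    iou_threshold: float = 0.5,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of detections to ground-truth boxes.

    Detections are visited in descending confidence (ties by input order);
    each claims the unclaimed truth box of highest IoU, provided that IoU
    reaches ``iou_threshold``.  Returns (matches as (det_idx, truth_idx)
    pairs, unmatched detection indices, unmatched truth indices).
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].conf, i))
    claimed: set[int] = set()
    matches: list[tuple[int, int]] = []
    unmatched_dets: list[int] = []
    for di in order:
        best_j, best_v = -1, 0.0
        for j, gt in enumerate(ground_truth):
            if j in claimed:
                continue
            v = iou(dets[di].box, gt)
            if v >= iou_threshold and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed.add(best_j)
            matches.append((di, best_j))
        else:
            unmatched_dets.append(di)
    unmatched_truth = [j for j in range(len(ground_truth)) if j not in claimed]
    return matches, unmatched_dets, unmatched_truth


def tally_bunches(
    matched_verdicts: Iterable[tuple[bool, bool]],
    spurious_predicted_qualified: Iterable[bool] = (),
    missed_truth_qualified: Iterable[bool] = (),
) -> ConfusionCounts:
    """Tally per-bunch verdicts into a confusion matrix.

    ``matched_verdicts`` holds (predicted_qualified, truth_qualified) pairs
    for detected bunches matched to ground truth.  Spurious detected
    bunches (no ground-truth match) are tallied against an implicit
    qualified truth; missed ground-truth bunches against an implicit
    qualified prediction.  Positive = unqualified, so e.g. a spurious bunch
    predicted unqualified contributes one FP.
    """
    tp = tn = fp = fn = 0
    for pred_q, true_q in matched_verdicts:
        if not pred_q and not true_q:
            tp += 1
        elif pred_q and true_q:
            tn += 1
        elif not pred_q and true_q:
            fp += 1
        else:
            fn += 1
    for pred_q in spurious_predicted_qualified:
        if pred_q:
            tn += 1
        else:
            fp += 1
    for true_q in missed_truth_qualified:
        if true_q:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class PRCurve:
    """Precision–recall points (recall non-decreasing) and their AP."""

    recalls: tuple[float, ...]
    precisions: tuple[float, ...]
    ap: float


def average_precision(
    recalls: Sequence[float], precisions: Sequence[float]
) -> float:
    """Area under the precision envelope, all-point interpolation.

    Precisions are first replaced by their running maximum from the right
    (the monotone envelope), then the area is summed over every recall
    increment.
    """
    if len(recalls) != len(precisions):
        raise ValueError("recalls and precisions must have equal length")
    if len(recalls) == 0:
        return 0.0
    r = np.concatenate(([0.0], np.asarray(recalls, dtype=float)))
    p = np.concatenate(([0.0], np.asarray(precisions, dtype=float)))
    if np.any(np.diff(r) < 0):
        raise ValueError("recalls must be non-decreasing")
    env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * env[1:]))


def pr_curve(
    dets: Sequence[Detection],
    ground_truth: Sequence[Box],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """Single-class PR curve from scored detections vs. truth boxes.

    Detections are ranked by confidence; each rank prefix yields one
    (recall, precision) point via greedy IoU matching of the prefix.
    Equivalent to the usual cumulative TP/FP construction because the
    greedy matching is itself confidence-ordered.
    """
    n_truth = len(ground_truth)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].conf, i))
    matches, _, _ = match_detections(dets, ground_truth, iou_threshold)
    matched_dets = {di for di, _ in matches}
    tp_flags = np.array([1 if di in matched_dets else 0 for di in order])
    if len(tp_flags) == 0 or n_truth == 0:
        return PRCurve((), (), 0.0)
    tp_cum = np.cumsum(tp_flags)
    ranks = np.arange(1, len(tp_flags) + 1)
    recalls = tuple(tp_cum / n_truth)
    precisions = tuple(tp_cum / ranks)
    return PRCurve(recalls, precisions, average_precision(recalls, precisions))


def mean_ap(per_class_ap: Sequence[float]) -> float:
    """Mean of per-class average precisions."""
    if not per_class_ap:
        return 0.0
    return float(np.mean(per_class_ap))


def _scene_counts(
    dets: Sequence[Detection],
    truth_bunches: Sequence[tuple[Box, int]],
    config: LooseningConfig,
    iou_match_threshold: float,
) -> ConfusionCounts:
    """Assess one scene and tally its bunch verdicts against ground truth."""
    assessments = assess_scene(list(dets), config)
    pred_boxes = [a.bunch for a in assessments]
    truth_boxes = [box for box, _ in truth_bunches]
    matches, spurious, missed = match_detections(
        pred_boxes, truth_boxes, iou_match_threshold
    )
    true_q = [x < config.lam for _, x in truth_bunches]
    pairs = [(assessments[di].qualified, true_q[tj]) for di, tj in matches]
    return tally_bunches(
        pairs,
        [assessments[di].qualified for di in spurious],
        [true_q[tj] for tj in missed],
    )


def confidence_sweep(
    scenes: Sequence[tuple[Sequence[Detection], Sequence[tuple[Box, int]]]],
    thresholds: Sequence[float],
    config: LooseningConfig = LooseningConfig(),
    iou_match_threshold: float = 0.5,
) -> list[SweepRow]:
    """Evaluate the bunch classifier across confidence cutoffs.

    ``scenes`` is a list of (detections, truth bunches) pairs, a truth
    bunch being (box, true member-stem count).  For each threshold the full
    pipeline is re-run at that cutoff, verdicts are tallied over all
    scenes, and precision/recall/F1 are computed from the pooled counts.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for thr in thresholds:
        cfg = LooseningConfig(config.lam, thr, config.multi_overlap_rule)
        counts = ConfusionCounts()
        for dets, truth in scenes:
            counts = counts + _scene_counts(dets, truth, cfg, iou_match_threshold)
        rows.append(SweepRow.from_counts(thr, counts))
    return rows


def sweep_from_counts(
    rows: Sequence[tuple[float, ConfusionCounts]]
) -> list[SweepRow]:
    """Build a sweep table from pre-tallied per-threshold confusion counts."""
    return [SweepRow.from_counts(thr, c) for thr, c in rows]


def best_threshold(rows: Sequence[SweepRow]) -> SweepRow:
    """The F1-maximizing row (first such row on ties)."""
    if not rows:
        raise ValueError("empty sweep")
    return max(rows, key=lambda r: (r.f1, -r.conf_threshold))
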