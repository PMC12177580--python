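"""Published conveyor-line trial tallies of the reference detector.

Two small data tables from the field trial that established the 0.30
operating point, shipped as plain constants so the evaluation machinery
can be exercised and cross-checked without the image dataset:

* the bunch-level confusion counts at five detection-confidence cutoffs
  (positive class = unqualified bunch);
* the per-bunch outcome list at the 0.30 cutoff — 37 detected bunches
  matched to ground truth, given as (truth qualified?, predicted
  qualified?) pairs — plus the three unmatched bunches: two spurious
  detections that were rated unqualified and one unqualified ground-truth
  bunch the detector missed.  That 2 + 1 split is the one consistent with
  the published confusion counts at 0.30.

These are raw inputs; every derived number (precision, recall, F1,
accuracies, the best threshold) is recomputed by the evaluation module.
"""

from __future__ import annotations

from .evaluation import ConfusionCounts

__all__ = [
    "conveyor_trial_sweep_counts",
    "conveyor_trial_bunch_records",
    "OPERATING_CONFIDENCE",
]

#: the trial's selected operating confidence threshold
OPERATING_CONFIDENCE = 0.30

_SWEEP_COUNTS: tuple[tuple[float, tuple[int, int, int, int]], ...] = (
    # (confidence, (tp, tn, fp, fn))
    (0.25, (24, 6, 9, 2)),
    (0.30, (23, 8, 6, 3)),
    (0.35, (17, 10, 3, 9)),
    (0.40, (9, 12, 1, 17)),
    (0.45, (5, 12, 0, 21)),
)

# Matched bunches at confidence 0.30, as (truth_qualified, predicted_qualified).
_T, _F = True, False
_BUNCH_ROWS: tuple[tuple[bool, bool], ...] = (
    (_F, _F), (_F, _F), (_F, _F), (_F, _F), (_T, _F), (_F, _F), (_T, _F),
    (_F, _F), (_F, _F), (_F, _F), (_F, _T), (_T, _T), (_T, _T), (_F, _F),
    (_F, _F), (_F, _F), (_F, _F), (_T, _F), (_F, _F), (_F, _F), (_F, _F),
    (_F, _F), (_F, _F), (_F, _F), (_T, _T), (_F, _F), (_F, _F), (_T, _T),
    (_T, _T), (_T, _T), (_T, _T), (_F, _F), (_F, _F), (_F, _F), (_T, _F),
    (_T, _T), (_F, _T),
)

#: predicted verdicts of the spurious detected bunches (qualified?)
_SPURIOUS_PREDICTED_QUALIFIED: tuple[bool, ...] = (False, False)
#: truth verdicts of the missed ground-truth bunches (qualified?)
_MISSED_TRUTH_QUALIFIED: tuple[bool, ...] = (False,)


def conveyor_trial_sweep_counts() -> list[tuple[float, ConfusionCounts]]:
    """Confusion counts at each trialled confidence threshold."""
    return [(thr, ConfusionCounts(*c)) for thr, c in _SWEEP_COUNTS]


def conveyor_trial_bunch_records() -> tuple[
    list[tuple[bool, bool]], list[bool], list[bool]
]:
    """Per-bunch records at the operating confidence.

    Returns (matched (predicted_qualified, truth_qualified) pairs, spurious
    predicted verdicts, missed truth verdicts) — the argument layout of
    :func:`loosenrate.evaluation.tally_bunches`.
    """
    matched = [(pred, truth) for truth, pred in _BUNCH_ROWS]
    return (
        matched,
        list(_SPURIOUS_PREDICTED_QUALIFIED),
        list(_MISSED_TRUTH_QUALIFIED),
    )
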