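"""Leaf-loosening rate computation from stem/bunch detections.

During conveyor-belt sorting, cured tobacco leaves must be spread out
("loosened") so individual leaves can be graded.  A detector labels each
visible object either ``stem`` (a single exposed leaf stem) or ``bunch``
(a region of overlapping stems, i.e. an insufficiently loosened bundle).
The loosening rate of a bunch with x overlapping member stems is

    R = λ / x × 100 %

where λ is the operator-set maximum number of stems an acceptably loosened
bunch may contain (default 8).  A bunch is *qualified* when x < λ
(equivalently R > 100 %) and *unqualified* otherwise — unqualified bunches
are the ones workers must re-loosen.

The pipeline: drop detections below the confidence threshold, split the
rest by class, count for each bunch the stems whose boxes overlap it with
positive area, then rate and classify each bunch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .geometry import Box, intersection_area

__all__ = [
    "ObjectClass",
    "Detection",
    "LooseningConfig",
    "BunchAssessment",
    "filter_by_confidence",
    "assign_stems_to_bunches",
    "loosening_rate",
    "classify_bunch",
    "assess_scene",
]

logger = logging.getLogger(__name__)


class ObjectClass(str, Enum):
    """The two annotation classes: a single stem vs. overlapping stems."""

    STEM = "stem"
    BUNCH = "bunch"


@dataclass(frozen=True)
class Detection:
    """One detector output record: box, confidence and class label."""

    box: Box
    conf: float
    label: ObjectClass

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence {self.conf} outside [0, 1]")
        if not isinstance(self.label, ObjectClass):
            object.__setattr__(self, "label", ObjectClass(self.label))


@dataclass(frozen=True)
class LooseningConfig:
    """Parameters of the loosening-rate algorithm.

    ``lam`` is λ, the largest stem count a qualified bunch may have; field
    staff set it per site (default 8).  ``conf_threshold`` is the detection
    confidence cutoff (default 0.30, the F1-maximizing operating point of
    the reference detector).  ``multi_overlap_rule`` decides where a stem
    overlapping several bunch boxes is counted: ``max_intersection`` assigns
    it to the bunch with the largest overlap area (ties to the lowest bunch
    index), ``all`` counts it in every overlapped bunch.
    """

    lam: int = 8
    conf_threshold: float = 0.30
    multi_overlap_rule: str = "max_intersection"

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if not (0.0 <= self.conf_threshold <= 1.0):
            raise ValueError(f"conf_threshold {self.conf_threshold} outside [0, 1]")
        if self.multi_overlap_rule not in ("max_intersection", "all"):
            raise ValueError(f"unknown multi_overlap_rule {self.multi_overlap_rule!r}")


@dataclass(frozen=True)
class BunchAssessment:
    """Verdict for one detected bunch: member count x, rate R, qualified flag.

    ``rate`` is in percent and is ``None`` for an empty bunch (x = 0), where
    λ/x is undefined; such bunches are reported qualified with a warning.
    """

    bunch: Detection
    x: int
    rate: float | None
    qualified: bool


def filter_by_confidence(dets: list[Detection], threshold: float) -> list[Detection]:
    """Keep detections with ``conf >= threshold``, preserving order."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [d for d in dets if d.conf >= threshold]


def assign_stems_to_bunches(
    stems: list[Detection],
    bunches: list[Detection],
    rule: str = "max_intersection",
) -> dict[int, int]:
    """Count, per bunch index, the stems overlapping that bunch box.

    Overlap means strictly positive intersection area; edge contact does not
    count.  Under ``max_intersection`` each stem contributes to at most one
    bunch — the one it overlaps most, ties broken toward the lowest bunch
    index.  Under ``all`` it contributes to every bunch it overlaps.  Stems
    overlapping no bunch contribute nowhere; every bunch index appears in
    the result, with 0 where no stem overlaps.
    """
    if rule not in ("max_intersection", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    counts = {i: 0 for i in range(len(bunches))}
    for stem in stems:
        overlaps = [
            (i, intersection_area(stem.box, bunch.box))
            for i, bunch in enumerate(bunches)
        ]
        overlaps = [(i, a) for i, a in overlaps if a > 0.0]
        if not overlaps:
            continue
        if rule == "all":
            for i, _ in overlaps:
                counts[i] += 1
        else:
            best = max(overlaps, key=lambda t: (t[1], -t[0]))
            counts[best[0]] += 1
    return counts


def loosening_rate(x: int, lam: int) -> float:
    """R = 100·λ/x percent; undefined (ValueError) at x = 0."""
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if x < 1:
        raise ValueError("loosening rate is undefined for an empty bunch (x = 0)")
    return 100.0 * lam / x


def classify_bunch(x: int, lam: int) -> bool:
    """True (qualified) iff x < λ; x = 0 is vacuously qualified, with a warning."""
    if x < 0:
        raise ValueError(f"stem count must be >= 0, got {x}")
    if x == 0:
        logger.warning(
            "bunch with no overlapping stem detections: reported qualified, "
            "but the detector may have failed to resolve its members"
        )
        return True
    return x < lam


def assess_scene(
    dets: list[Detection], config: LooseningConfig = LooseningConfig()
) -> list[BunchAssessment]:
    """Run the full per-scene pipeline; one assessment per surviving bunch.

    Deterministic for fixed input.  A scene with no bunch detections returns
    an empty list, which downstream consumers read as fully qualified.
    """
    kept = filter_by_confidence(dets, config.conf_threshold)
    stems = [d for d in kept if d.label is ObjectClass.STEM]
    bunches = [d for d in kept if d.label is ObjectClass.BUNCH]
    counts = assign_stems_to_bunches(stems, bunches, config.multi_overlap_rule)
    out = []
    for i, bunch in enumerate(bunches):
        x = counts[i]
        rate = loosening_rate(x, config.lam) if x >= 1 else None
        out.append(BunchAssessment(bunch, x, rate, classify_bunch(x, config.lam)))
    return out
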