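"""Axis-aligned bounding-box arithmetic.

Boxes live in continuous pixel coordinates, origin at the image top-left
corner, x increasing rightward and y increasing downward.  Every loss
function, the stem/bunch association predicate and the detection matcher
are built on the four operations defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Box",
    "iou",
    "intersection_area",
    "union_area",
    "enclosing_box",
    "center_distance_sq",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle ``(x1, y1) .. (x2, y2)`` with strictly positive area.

    ``(x1, y1)`` is the top-left corner and ``(x2, y2)`` the bottom-right
    corner.  Width, height, center and area are derived properties; they are
    never stored separately so they cannot drift out of sync.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2}) "
                "requires x2 > x1 and y2 > y1"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        """Build a box from center coordinates and size (the YOLO label layout)."""
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def intersection_area(a: Box, b: Box) -> float:
    """Overlap area of two boxes; 0 when disjoint or merely edge-touching."""
    w = min(a.x2, b.x2) - max(a.x1, b.x1)
    h = min(a.y2, b.y2) - max(a.y1, b.y1)
    if w <= 0 or h <= 0:
        return 0.0
    return w * h


def union_area(a: Box, b: Box) -> float:
    return a.area + b.area - intersection_area(a, b)


def iou(a: Box, b: Box) -> float:
    """Intersection over union, in [0, 1]; symmetric in its arguments."""
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def enclosing_box(a: Box, b: Box) -> Box:
    """Smallest axis-aligned box covering both inputs."""
    return Box(
        min(a.x1, b.x1), min(a.y1, b.y1), max(a.x2, b.x2), max(a.y2, b.y2)
    )


def center_distance_sq(a: Box, b: Box) -> float:
    """Squared Euclidean distance between box centers (pixels squared)."""
    (ax, ay), (bx, by) = a.center, b.center
    return (ax - bx) ** 2 + (ay - by) ** 2


def center_distance(a: Box, b: Box) -> float:
    return math.sqrt(center_distance_sq(a, b))
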