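"""Readers and writers for the two text formats the pipeline touches.

* YOLO label files: one object per line, ``class_id cx cy w h`` with
  center/size coordinates normalized to [0, 1].
* Detection files: one detection per line, ``x1 y1 x2 y2 conf class_id``
  in pixel corner coordinates — the detector's output contract — either as
  whitespace-separated text (``#`` comments allowed) or as a JSON array of
  6-element rows.

Readers reject malformed input with errors naming the file and line
rather than silently coercing; writers round-trip losslessly with their
matching reader to at least six decimal places.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .geometry import Box
from .loosening import Detection, ObjectClass

__all__ = [
    "DEFAULT_CLASS_MAP",
    "read_yolo_labels",
    "read_detections",
    "write_detections",
    "write_labels",
]

#: default class-id mapping; the dataset's id order is a convention, so it
#: stays configurable everywhere it is used.
DEFAULT_CLASS_MAP: dict[str, int] = {"stem": 0, "bunch": 1}


class ParseError(ValueError):
    """Malformed input file; message carries file path and line number."""


def _invert(class_map: dict[str, int]) -> dict[int, ObjectClass]:
    return {v: ObjectClass(k) for k, v in class_map.items()}


def read_yolo_labels(
    path: str | Path,
    image_size: tuple[int, int],
    class_map: dict[str, int] = DEFAULT_CLASS_MAP,
) -> list[Detection]:
    """Read a YOLO-format label file into corner-format detections (conf = 1).

    ``image_size`` is (width, height) in pixels; normalized center/size
    coordinates are scaled by it.  Blank lines are skipped.
    """
    path = Path(path)
    width, height = image_size
    id_to_class = _invert(class_map)
    out: list[Detection] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            class_id = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 <= v <= 1.0):
                raise ParseError(
                    f"{path}:{lineno}: {name}={v} outside normalized range [0, 1]"
                )
        if class_id not in id_to_class:
            raise ParseError(f"{path}:{lineno}: unknown class id {class_id}")
        box = Box.from_center(cx * width, cy * height, w * width, h * height)
        out.append(Detection(box, 1.0, id_to_class[class_id]))
    return out


def _detection_from_row(
    row: Sequence[float], where: str, id_to_class: dict[int, ObjectClass]
) -> Detection:
    if len(row) != 6:
        raise ParseError(f"{where}: expected 6 values, got {len(row)}")
    x1, y1, x2, y2, conf, class_id = (float(v) for v in row)
    if not (0.0 <= conf <= 1.0):
        raise ParseError(f"{where}: confidence {conf} outside [0, 1]")
    if int(class_id) != class_id or int(class_id) not in id_to_class:
        raise ParseError(f"{where}: unknown class id {class_id}")
    try:
        box = Box(x1, y1, x2, y2)
    except ValueError as exc:
        raise ParseError(f"{where}: {exc}") from None
    return Detection(box, conf, id_to_class[int(class_id)])


def read_detections(
    path: str | Path, class_map: dict[str, int] = DEFAULT_CLASS_MAP
) -> list[Detection]:
    """Read a detection file (``x1 y1 x2 y2 conf class`` rows, text or JSON)."""
    path = Path(path)
    id_to_class = _invert(class_map)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        try:
            rows = json.loads(text) if text.strip() else []
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from None
        return [
            _detection_from_row(row, f"{path}: row {i}", id_to_class)
            for i, row in enumerate(rows)
        ]
    out: list[Detection] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            values = [float(p) for p in line.split()]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        out.append(_detection_from_row(values, f"{path}:{lineno}", id_to_class))
    return out


def write_detections(
    dets: Sequence[Detection],
    path: str | Path,
    class_map: dict[str, int] = DEFAULT_CLASS_MAP,
) -> None:
    """Write detections as ``x1 y1 x2 y2 conf class`` text rows (6 decimals)."""
    lines = []
    for d in dets:
        b = d.box
        lines.append(
            f"{b.x1:.6f} {b.y1:.6f} {b.x2:.6f} {b.y2:.6f} "
            f"{d.conf:.6f} {class_map[d.label.value]}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_labels(
    dets: Sequence[Detection],
    path: str | Path,
    image_size: tuple[int, int],
    class_map: dict[str, int] = DEFAULT_CLASS_MAP,
) -> None:
    """Write objects as YOLO-format normalized labels (confidence dropped)."""
    width, height = image_size
    lines = []
    for d in dets:
        cx, cy = d.box.center
        lines.append(
            f"{class_map[d.label.value]} {cx / width:.6f} {cy / height:.6f} "
            f"{d.box.width / width:.6f} {d.box.height / height:.6f}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
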