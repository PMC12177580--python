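"""Run configuration: defaults, YAML/JSON loading, validation.

Unknown keys are rejected rather than ignored so a typo in a config file
fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .io import DEFAULT_CLASS_MAP

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Every tunable the CLI and pipeline consume.

    ``lam`` (λ) is the qualified-bunch stem cap, default 8;
    ``conf_threshold`` the detection cutoff, default 0.30 (the operating
    point that maximizes bunch-classification F1 for the reference
    detector).  ``loss`` names a registry entry; ``gamma`` and
    ``momentum`` parameterize the WIoU v2 focusing mechanism and ``eps``
    the fusion stabilizer.
    """

    lam: int = 8
    conf_threshold: float = 0.30
    class_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    iou_match_threshold: float = 0.5
    image_width: int = 2448
    image_height: int = 2048
    loss: str = "wiou_v2"
    gamma: float = 1.0
    momentum: float = 0.01
    eps: float = 1e-4
    sweep_thresholds: list[float] = field(
        default_factory=lambda: [0.25, 0.30, 0.35, 0.40, 0.45]
    )
    multi_overlap_rule: str = "max_intersection"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        for name in ("conf_threshold", "iou_match_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image size must be positive")
        if sorted(self.class_map.values()) != list(range(len(self.class_map))):
            raise ValueError(f"class ids must be 0..{len(self.class_map) - 1}")
        if set(self.class_map) != {"stem", "bunch"}:
            raise ValueError("class_map must map exactly 'stem' and 'bunch'")
        if not (0.0 < self.momentum <= 1.0):
            raise ValueError(f"momentum {self.momentum} outside (0, 1]")
        if self.gamma < 0 or self.eps <= 0:
            raise ValueError("gamma must be >= 0 and eps > 0")
        if self.sweep_thresholds != sorted(self.sweep_thresholds):
            raise ValueError("sweep_thresholds must be sorted ascending")
        if self.multi_overlap_rule not in ("max_intersection", "all"):
            raise ValueError(f"unknown multi_overlap_rule {self.multi_overlap_rule!r}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) config; missing file keys default.

    ``None`` or an empty file yields all defaults.  Unknown keys raise.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    # accept the field name users expect for λ
    if "lambda" in raw:
        raw["lam"] = raw.pop("lambda")
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
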