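"""Fast-normalized weighted feature fusion (BiFPN node arithmetic).

A bidirectional feature pyramid fuses each level's input with a resized
neighbor level through learnable non-negative weights normalized by their
sum plus a small stabilizer ε:

    td  = transform( (w1·P_in + w2·resize(P_higher)) / (w1 + w2 + ε) )
    out = transform( (w1'·P_in + w2'·P_td + w3'·resize(P_lower_out))
                     / (w1' + w2' + w3' + ε) )

Only the fusion arithmetic lives here; the per-node convolution and the
resize operator are injected callables, so the math is testable without a
network.  Defaults: identity transform, nearest-neighbor 2× upsampling and
2×2 average-pool downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FeatureGrid",
    "FusionWeights",
    "fuse",
    "td_node",
    "out_node",
    "upsample_nearest",
    "downsample_avg",
]

#: pyramid levels, fine to coarse; spatial size halves per step (160/80/40/20
#: at a 640-pixel input).
LEVELS = ("P2", "P3", "P4", "P5")

Transform = Callable[[np.ndarray], np.ndarray]
Resize = Callable[[np.ndarray], np.ndarray]


def _identity(values: np.ndarray) -> np.ndarray:
    return values


@dataclass(frozen=True)
class FeatureGrid:
    """A pyramid level's feature map: a 2-D (or 2-D + channel) real array."""

    values: np.ndarray
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown pyramid level {self.level!r}; expected one of {LEVELS}")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim not in (2, 3):
            raise ValueError(f"feature grid must be 2-D or 3-D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature grid contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def level_index(self) -> int:
        return LEVELS.index(self.level)


@dataclass(frozen=True)
class FusionWeights:
    """Per-input raw fusion weights plus the normalization stabilizer ε.

    Negative raw weights are clamped to zero at use (the standard relaxation
    of the non-negativity constraint on learned fusion weights).
    """

    w: tuple[float, ...]
    eps: float = 1e-4

    def __init__(self, w: Sequence[float], eps: float = 1e-4) -> None:
        if eps < 0:
            raise ValueError(f"eps must be >= 0, got {eps}")
        object.__setattr__(self, "w", tuple(float(x) for x in w))
        object.__setattr__(self, "eps", float(eps))

    @property
    def clamped(self) -> np.ndarray:
        return np.maximum(np.asarray(self.w), 0.0)


def upsample_nearest(values: np.ndarray, factor: int = 2) -> np.ndarray:
    """Nearest-neighbor upsampling of the two leading spatial axes."""
    return values.repeat(factor, axis=0).repeat(factor, axis=1)


def downsample_avg(values: np.ndarray, factor: int = 2) -> np.ndarray:
    """Average-pool downsampling (factor×factor blocks) of the spatial axes."""
    h, w = values.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"spatial shape {(h, w)} not divisible by {factor}")
    trailing = values.shape[2:]
    blocked = values.reshape(h // factor, factor, w // factor, factor, *trailing)
    return blocked.mean(axis=(1, 3))


def fuse(
    inputs: Sequence[FeatureGrid],
    weights: FusionWeights,
    transform: Transform | None = None,
) -> FeatureGrid:
    """Weighted fast-normalized fusion of same-shape feature grids.

    Returns ``transform(Σ wᵢ·inputᵢ / (Σ wᵢ + ε))`` at the level of the first
    input.  With the identity transform the output is a near-convex
    combination of the inputs (exactly convex as ε → 0), hence bounded by
    their elementwise min and max.
    """
    if len(inputs) < 2:
        raise ValueError("fusion needs at least two inputs")
    w = weights.clamped
    if len(w) != len(inputs):
        raise ValueError(f"{len(w)} weights for {len(inputs)} inputs")
    shape = inputs[0].values.shape
    for grid in inputs[1:]:
        if grid.values.shape != shape:
            raise ValueError(f"shape mismatch: {grid.values.shape} vs {shape}")
    denom = w.sum() + weights.eps
    if denom == 0.0:
        raise ValueError("all weights zero with eps = 0: fusion undefined")
    numer = sum(wi * grid.values for wi, grid in zip(w, inputs))
    fused = numer / denom
    transform = transform or _identity
    return FeatureGrid(transform(fused), inputs[0].level)


def _check_adjacent(fine: FeatureGrid, coarse: FeatureGrid) -> None:
    if coarse.level_index != fine.level_index + 1:
        raise ValueError(
            f"{coarse.level} is not one pyramid step coarser than {fine.level}"
        )


def td_node(
    same_level: FeatureGrid,
    higher_level: FeatureGrid,
    weights: FusionWeights,
    resize: Resize = upsample_nearest,
    transform: Transform | None = None,
) -> FeatureGrid:
    """Top-down node: fuse a level's input with the upsampled coarser level."""
    _check_adjacent(same_level, higher_level)
    resized = FeatureGrid(resize(higher_level.values), same_level.level)
    return fuse([same_level, resized], weights, transform)


def out_node(
    level_in: FeatureGrid,
    level_td: FeatureGrid,
    lower_out: FeatureGrid,
    weights: FusionWeights,
    resize: Resize = downsample_avg,
    transform: Transform | None = None,
) -> FeatureGrid:
    """Bottom-up output node: fuse input, top-down and downsampled finer output."""
    if level_td.level != level_in.level:
        raise ValueError(f"level mismatch: {level_td.level} vs {level_in.level}")
    _check_adjacent(lower_out, level_in)
    resized = FeatureGrid(resize(lower_out.values), level_in.level)
    return fuse([level_in, level_td, resized], weights, transform)
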