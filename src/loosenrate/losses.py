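"""IoU-family bounding-box regression losses as pure scalar functions.

Implements the loss the detector trains with (WIoU v2, a distance-aware
exponential penalty with a monotonic focusing multiplier driven by a
running mean of the IoU loss) together with the losses it is compared
against: CIoU (the YOLOv8 default), GIoU, DIoU, EIoU and Focal-EIoU.

Every loss maps a (predicted, ground-truth) box pair to a non-negative
scalar plus named intermediate components, so any value can be inspected
or re-derived in a test.  Batching and reduction are the caller's concern;
these are per-pair scalars usable inside any training loop.

The WIoU formulation treats the enclosing-box normalizer ``W_g² + H_g²`` as
a constant under differentiation.  A scalar library has no gradients, so
the contract is honored by reporting that normalizer among the components,
letting an autodiff consumer detach it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .geometry import Box, center_distance_sq, enclosing_box, iou, union_area

__all__ = [
    "LossResult",
    "WIoUState",
    "ciou_loss",
    "wiou_v1_loss",
    "wiou_v2_loss",
    "giou_loss",
    "diou_loss",
    "eiou_loss",
    "focal_eiou_loss",
    "comparator_loss",
    "get_loss",
    "LOSS_REGISTRY",
]

#: floor applied to the running-mean divisor of the focusing multiplier;
#: the multiplier is undefined at mean exactly 0.
EPS_MEAN = 1e-8


@dataclass(frozen=True)
class LossResult:
    """A scalar loss value plus its named intermediate quantities."""

    value: float
    components: dict[str, float] = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


@dataclass
class WIoUState:
    """Running state of the monotonic focusing mechanism (WIoU v2).

    Parameters
    ----------
    running_mean_liou:
        Exponential moving average of the IoU loss over observed pairs.
        Starts at 1.0, the neutral multiplier for the first sample under
        ``gamma = 1`` when the IoU loss itself is 1.
    momentum:
        EMA update weight in (0, 1]; ``new = (1 - m) * old + m * value``.
    gamma:
        Focusing exponent γ ≥ 0.  γ = 0 disables focusing entirely.
    """

    running_mean_liou: float = 1.0
    momentum: float = 0.01
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.momentum <= 1.0):
            raise ValueError(f"momentum must be in (0, 1], got {self.momentum}")
        if self.gamma < 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.running_mean_liou < 0.0:
            raise ValueError("running_mean_liou must be >= 0")

    def update(self, liou: float) -> None:
        self.running_mean_liou = (
            (1.0 - self.momentum) * self.running_mean_liou + self.momentum * liou
        )


def ciou_loss(pred: Box, gt: Box) -> LossResult:
    """Complete-IoU loss: ``1 − IoU + ρ²/c² + α·v``.

    ``ρ²`` is the squared center distance, ``c²`` the squared diagonal of the
    smallest enclosing box, ``v`` the aspect-ratio consistency term
    ``(4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²`` and ``α = v/((1−IoU)+v)``.
    When the boxes coincide both the numerator and denominator of α vanish;
    the α·v term is defined as 0 there (its limit).
    """
    i = iou(pred, gt)
    rho2 = center_distance_sq(pred, gt)
    enc = enclosing_box(pred, gt)
    c2 = enc.width**2 + enc.height**2
    v = (4.0 / math.pi**2) * (
        math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)
    ) ** 2
    denom = (1.0 - i) + v
    alpha = v / denom if denom > 0.0 else 0.0
    value = 1.0 - i + rho2 / c2 + alpha * v
    return LossResult(
        value,
        {"iou": i, "rho2": rho2, "c2": c2, "v": v, "alpha": alpha,
         "penalty": rho2 / c2 + alpha * v},
    )


def wiou_v1_loss(pred: Box, gt: Box) -> LossResult:
    """WIoU v1: ``R_WIoU · L_IoU`` with an exponential center-distance penalty.

    ``R_WIoU = exp(ρ² / (W_g² + H_g²))`` where ``W_g, H_g`` are the enclosing
    box width and height, and ``L_IoU = 1 − IoU``.
    """
    liou = 1.0 - iou(pred, gt)
    rho2 = center_distance_sq(pred, gt)
    enc = enclosing_box(pred, gt)
    norm = enc.width**2 + enc.height**2  # detached under differentiation
    r_wiou = math.exp(rho2 / norm)
    return LossResult(
        r_wiou * liou,
        {"iou": 1.0 - liou, "liou": liou, "r_wiou": r_wiou,
         "rho2": rho2, "wg2_plus_hg2": norm},
    )


def wiou_v2_loss(pred: Box, gt: Box, state: WIoUState) -> LossResult:
    """WIoU v2: v1 scaled by the monotonic focusing coefficient.

    ``L = (L_IoU / mean(L_IoU))^γ · L_WIoUv1``.  The multiplier uses the
    running mean as it stood *before* this pair; ``state`` is then updated in
    place with the observed ``L_IoU``.  Pairs with small IoU loss (easy
    samples, already well localized) are down-weighted relative to the
    running average, concentrating the loss on hard, occluded objects.
    """
    v1 = wiou_v1_loss(pred, gt)
    liou = v1.components["liou"]
    mean = max(state.running_mean_liou, EPS_MEAN)
    focus = (liou / mean) ** state.gamma
    state.update(liou)
    return LossResult(
        focus * v1.value,
        {**v1.components, "focus": focus, "mean_liou_used": mean},
    )


def giou_loss(pred: Box, gt: Box) -> LossResult:
    """Generalized IoU loss: ``1 − IoU + |C \\ (A∪B)| / |C|``."""
    i = iou(pred, gt)
    enc = enclosing_box(pred, gt)
    u = union_area(pred, gt)
    giou = i - (enc.area - u) / enc.area
    return LossResult(1.0 - giou, {"iou": i, "giou": giou, "enclosing_area": enc.area})


def diou_loss(pred: Box, gt: Box) -> LossResult:
    """Distance-IoU loss: ``1 − IoU + ρ²/c²``."""
    i = iou(pred, gt)
    rho2 = center_distance_sq(pred, gt)
    enc = enclosing_box(pred, gt)
    c2 = enc.width**2 + enc.height**2
    return LossResult(1.0 - i + rho2 / c2, {"iou": i, "rho2": rho2, "c2": c2})


def eiou_loss(pred: Box, gt: Box) -> LossResult:
    """Efficient-IoU loss: DIoU plus separate width and height distance terms.

    ``1 − IoU + ρ²/c² + (w−w_gt)²/W_g² + (h−h_gt)²/H_g²`` with ``W_g, H_g``
    the enclosing-box width and height.
    """
    i = iou(pred, gt)
    rho2 = center_distance_sq(pred, gt)
    enc = enclosing_box(pred, gt)
    c2 = enc.width**2 + enc.height**2
    dw2 = (pred.width - gt.width) ** 2 / enc.width**2
    dh2 = (pred.height - gt.height) ** 2 / enc.height**2
    return LossResult(
        1.0 - i + rho2 / c2 + dw2 + dh2,
        {"iou": i, "rho2": rho2, "c2": c2, "w_term": dw2, "h_term": dh2},
    )


def focal_eiou_loss(pred: Box, gt: Box, focal_gamma: float = 0.5) -> LossResult:
    """Focal-EIoU: EIoU re-weighted by ``IoU^γ`` to emphasize high-overlap pairs."""
    base = eiou_loss(pred, gt)
    i = base.components["iou"]
    weight = i**focal_gamma
    return LossResult(weight * base.value, {**base.components, "focal_weight": weight})


LOSS_REGISTRY: dict[str, Callable[[Box, Box], LossResult]] = {
    "ciou": ciou_loss,
    "wiou_v1": wiou_v1_loss,
    "giou": giou_loss,
    "diou": diou_loss,
    "eiou": eiou_loss,
    "focal_eiou": focal_eiou_loss,
}


def get_loss(name: str) -> Callable[[Box, Box], LossResult]:
    """Look up a stateless loss by registry name (``loss: wiou_v1`` in config).

    ``wiou_v2`` is stateful; construct a :class:`WIoUState` and call
    :func:`wiou_v2_loss` directly, or use the CLI which does so.
    """
    try:
        return LOSS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown loss {name!r}; available: {sorted(LOSS_REGISTRY)} (+ wiou_v2)"
        ) from None


def comparator_loss(name: str, pred: Box, gt: Box) -> LossResult:
    """Evaluate a named comparator loss (giou / diou / eiou / focal_eiou / ciou)."""
    return get_loss(name)(pred, gt)
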