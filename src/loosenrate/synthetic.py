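"""Synthetic conveyor-belt scene generator with a detector-noise model.

Emulates the darkroom acquisition geometry — 2448×2048-pixel frames of a
conveyor carrying loosened tobacco leaves — as abstract bounding-box
scenes: isolated ``stem`` objects scattered over the belt plus ``bunch``
regions, each containing a configurable number of member stems.  Bunch
boxes are placed pairwise disjoint and member stems strictly inside their
bunch box, so the ground-truth stem↔bunch association is unambiguous and
every pipeline stage can be tested end to end with no image data.

A separate noise model corrupts the ground truth into simulated detector
output: per-object misses, Gaussian box-corner jitter, Poisson-distributed
spurious boxes, and confidence scores drawn from separate laws for true
(high) and spurious (low) detections.  The confidence laws are test
fixtures chosen to separate the two populations, not measured detector
behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .geometry import Box, intersection_area
from .loosening import Detection, ObjectClass

__all__ = ["SceneSpec", "NoiseModel", "Scene", "generate_scene", "corrupt",
           "generate_dataset", "simulate_survey"]

#: placement attempts before a crowded spec is declared unsatisfiable
MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one synthetic frame.

    ``bunch_sizes[i]`` is the true member-stem count x of bunch *i*.
    Sizes are pixel ranges sampled uniformly; stems default to 80–300 px
    per side (matching the small normalized label sizes typical of single
    stems at this resolution) and bunch boxes to 400–800 px.
    """

    image_width: int = 2448
    image_height: int = 2048
    n_isolated_stems: int = 10
    bunch_sizes: tuple[int, ...] = (4, 10)
    stem_size_range: tuple[float, float] = (80.0, 300.0)
    bunch_size_range: tuple[float, float] = (400.0, 800.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bunch_sizes", tuple(int(x) for x in self.bunch_sizes))
        if any(x < 0 for x in self.bunch_sizes):
            raise ValueError("bunch sizes must be non-negative")
        if self.n_isolated_stems < 0:
            raise ValueError("n_isolated_stems must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Detector-imperfection model applied to a ground-truth scene.

    ``p_miss`` — probability each true object goes undetected;
    ``fp_rate`` — expected spurious detections per scene (Poisson);
    ``jitter_sd`` — standard deviation, in pixels, of independent Gaussian
    perturbations of each box corner (boxes re-clamped to stay valid);
    ``conf_true`` / ``conf_spurious`` — Beta(a, b) parameters of the
    confidence laws for surviving true objects and spurious boxes
    (defaults mean 0.8 and 0.3 respectively); ``conf_true = None`` keeps
    each true object's own confidence (the fully-noiseless identity case);
    ``p_spurious_bunch`` — chance a spurious box is labelled bunch rather
    than stem (bunches are rare on a real belt);
    ``p_spurious_in_bunch`` — chance a spurious *stem* is a ghost detection
    placed inside a random bunch box rather than anywhere on the belt.
    Detector hallucinations concentrate in cluttered regions, and it is
    these ghosts that inflate member counts at permissive thresholds.
    """

    p_miss: float = 0.1
    fp_rate: float = 6.0
    jitter_sd: float = 3.0
    conf_true: tuple[float, float] | None = (8.0, 2.0)
    conf_spurious: tuple[float, float] = (3.0, 7.0)
    p_spurious_bunch: float = 0.15
    p_spurious_in_bunch: float = 0.7

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_spurious_bunch", "p_spurious_in_bunch"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be non-negative")


ZERO_NOISE = NoiseModel(p_miss=0.0, fp_rate=0.0, jitter_sd=0.0, conf_true=None)


@dataclass(frozen=True)
class Scene:
    """Ground truth for one frame: objects at confidence 1 plus true counts.

    ``objects`` lists every truth box; ``bunch_x`` aligns with the bunch
    objects in order of appearance and holds each bunch's true member count.
    """

    spec: SceneSpec
    objects: tuple[Detection, ...]
    bunch_x: tuple[int, ...]

    @property
    def bunches(self) -> list[Detection]:
        return [d for d in self.objects if d.label is ObjectClass.BUNCH]

    @property
    def stems(self) -> list[Detection]:
        return [d for d in self.objects if d.label is ObjectClass.STEM]

    def truth_bunches(self) -> list[tuple[Box, int]]:
        """(box, true x) pairs in bunch order — the evaluation contract."""
        return [(b.box, x) for b, x in zip(self.bunches, self.bunch_x)]


def _sample_box(
    rng: np.random.Generator,
    size_range: tuple[float, float],
    width: int,
    height: int,
) -> Box:
    w = rng.uniform(*size_range)
    h = rng.uniform(*size_range)
    w, h = min(w, width - 1), min(h, height - 1)
    x1 = rng.uniform(0, width - w)
    y1 = rng.uniform(0, height - h)
    return Box(x1, y1, x1 + w, y1 + h)


def _contained_box(
    rng: np.random.Generator, outer: Box, size_range: tuple[float, float]
) -> Box:
    w = min(rng.uniform(*size_range), outer.width * 0.9)
    h = min(rng.uniform(*size_range), outer.height * 0.9)
    x1 = rng.uniform(outer.x1, outer.x2 - w)
    y1 = rng.uniform(outer.y1, outer.y2 - h)
    return Box(x1, y1, x1 + w, y1 + h)


def generate_scene(spec: SceneSpec) -> Scene:
    """Deterministically generate a ground-truth scene from its spec.

    Bunch boxes are rejection-sampled to be pairwise disjoint; member
    stems are placed inside their bunch box (hence overlap it with
    positive area and no other bunch); isolated stems are rejection-sampled
    to overlap no bunch box.  Raises ``RuntimeError`` if a crowded spec
    exhausts the placement-attempt cap.
    """
    rng = np.random.default_rng(spec.seed)
    W, H = spec.image_width, spec.image_height

    bunch_boxes: list[Box] = []
    for _ in spec.bunch_sizes:
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            cand = _sample_box(rng, spec.bunch_size_range, W, H)
            if all(intersection_area(cand, b) == 0.0 for b in bunch_boxes):
                bunch_boxes.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {len(spec.bunch_sizes)} disjoint bunch boxes "
                f"in {W}x{H} after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )

    objects: list[Detection] = []
    for bunch_box, x in zip(bunch_boxes, spec.bunch_sizes):
        objects.append(Detection(bunch_box, 1.0, ObjectClass.BUNCH))
        for _ in range(x):
            stem = _contained_box(rng, bunch_box, spec.stem_size_range)
            objects.append(Detection(stem, 1.0, ObjectClass.STEM))

    # isolated stems keep a 1-px margin from every bunch box so coordinate
    # rounding in text round-trips cannot create a spurious overlap
    expanded = [
        Box(max(b.x1 - 1, 0), max(b.y1 - 1, 0), min(b.x2 + 1, W), min(b.y2 + 1, H))
        for b in bunch_boxes
    ]
    for _ in range(spec.n_isolated_stems):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            cand = _sample_box(rng, spec.stem_size_range, W, H)
            if all(intersection_area(cand, b) == 0.0 for b in expanded):
                objects.append(Detection(cand, 1.0, ObjectClass.STEM))
                break
        else:
            raise RuntimeError("could not place an isolated stem clear of all bunches")

    return Scene(spec, tuple(objects), tuple(spec.bunch_sizes))


def _jitter_box(
    rng: np.random.Generator, box: Box, sd: float, width: int, height: int
) -> Box:
    if sd == 0.0:
        return box
    x1, y1, x2, y2 = (
        box.x1 + rng.normal(0, sd),
        box.y1 + rng.normal(0, sd),
        box.x2 + rng.normal(0, sd),
        box.y2 + rng.normal(0, sd),
    )
    x1, x2 = sorted((x1, x2))
    y1, y2 = sorted((y1, y2))
    x1, y1 = max(0.0, x1), max(0.0, y1)
    x2, y2 = min(float(width), x2), min(float(height), y2)
    # enforce a minimum 1-px extent after clamping
    if x2 - x1 < 1.0:
        x2 = min(float(width), x1 + 1.0)
        x1 = x2 - 1.0
    if y2 - y1 < 1.0:
        y2 = min(float(height), y1 + 1.0)
        y1 = y2 - 1.0
    return Box(x1, y1, x2, y2)


def corrupt(scene: Scene, noise: NoiseModel, seed: int) -> list[Detection]:
    """Simulate detector output: misses, jitter, spurious boxes, confidences."""
    rng = np.random.default_rng(seed)
    spec = scene.spec
    out: list[Detection] = []
    for obj in scene.objects:
        if rng.uniform() < noise.p_miss:
            continue
        box = _jitter_box(rng, obj.box, noise.jitter_sd,
                          spec.image_width, spec.image_height)
        conf = obj.conf if noise.conf_true is None else float(rng.beta(*noise.conf_true))
        out.append(Detection(box, conf, obj.label))
    n_spurious = int(rng.poisson(noise.fp_rate))
    bunch_boxes = [b.box for b in scene.bunches]
    for _ in range(n_spurious):
        is_bunch = rng.uniform() < noise.p_spurious_bunch
        if (
            not is_bunch
            and bunch_boxes
            and rng.uniform() < noise.p_spurious_in_bunch
        ):
            # ghost stem inside a cluttered region
            host = bunch_boxes[int(rng.integers(len(bunch_boxes)))]
            box = _contained_box(rng, host, spec.stem_size_range)
        else:
            size_range = spec.bunch_size_range if is_bunch else spec.stem_size_range
            box = _sample_box(rng, size_range, spec.image_width, spec.image_height)
        conf = float(rng.beta(*noise.conf_spurious))
        out.append(Detection(
            box, conf, ObjectClass.BUNCH if is_bunch else ObjectClass.STEM
        ))
    return out


def simulate_survey(
    n_scenes: int,
    seed: int,
    noise: NoiseModel | None = None,
    bunches_per_scene: tuple[int, int] = (1, 3),
    bunch_size_range: tuple[int, int] = (2, 12),
    n_isolated_stems: int = 8,
) -> list[tuple[list[Detection], list[tuple[Box, int]]]]:
    """Sample a batch of scenes with simulated detections — the evaluation input.

    Bunch member counts are uniform over ``bunch_size_range`` (inclusive), a
    range straddling the default λ = 8 so both verdicts occur.  ``noise``
    defaults to :class:`NoiseModel`'s defaults; pass :data:`ZERO_NOISE` for
    an exact copy of the ground truth.  Returns per scene the simulated
    detections plus the (bunch box, true x) ground-truth pairs.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_scenes):
        n_bunches = int(rng.integers(bunches_per_scene[0], bunches_per_scene[1] + 1))
        sizes = tuple(
            int(rng.integers(bunch_size_range[0], bunch_size_range[1] + 1))
            for _ in range(n_bunches)
        )
        spec = SceneSpec(
            n_isolated_stems=n_isolated_stems,
            bunch_sizes=sizes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = generate_scene(spec)
        dets = corrupt(scene, noise, seed=int(rng.integers(0, 2**31 - 1)))
        out.append((dets, scene.truth_bunches()))
    return out


def generate_dataset(
    n_scenes: int,
    spec_sampler: Callable[[int], SceneSpec],
    noise: NoiseModel,
    out_dir: str | Path,
    lam: int = 8,
    noise_seed_offset: int = 10_000,
) -> dict:
    """Write a synthetic dataset: per scene a YOLO truth label file, a
    detection file in the ``[x1 y1 x2 y2 conf class]`` layout, and a JSON
    manifest of true per-bunch counts and verdicts.

    ``spec_sampler(i)`` supplies scene *i*'s spec (including its seed), so
    a rerun with the same sampler is byte-identical.  Returns the manifest.
    """
    from .io import write_detections, write_labels

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"lam": lam, "scenes": []}
    for i in range(n_scenes):
        spec = spec_sampler(i)
        scene = generate_scene(spec)
        dets = corrupt(scene, noise, seed=spec.seed + noise_seed_offset)
        label_path = out_dir / f"scene_{i:04d}_labels.txt"
        det_path = out_dir / f"scene_{i:04d}_detections.txt"
        write_labels(list(scene.objects), label_path,
                     (spec.image_width, spec.image_height))
        write_detections(dets, det_path)
        manifest["scenes"].append({
            "index": i,
            "labels": label_path.name,
            "detections": det_path.name,
            "image_size": [spec.image_width, spec.image_height],
            "bunch_x": list(scene.bunch_x),
            "bunch_qualified": [x < lam for x in scene.bunch_x],
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
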