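# Methods

## The loosening-rate procedure

The pipeline maps a scene's detections to per-bunch verdicts in five
deterministic steps: (1) drop detections with confidence below the
threshold (the boundary survives: `conf >= t`); (2) split the survivors
into `stem` and `bunch` sets by class label; (3) for every stem, find the
bunch boxes it overlaps with strictly positive intersection area —
edge-touching boxes do not overlap, consistent with area-based IoU; (4)
count members per bunch; (5) rate each bunch R = 100·λ/x and classify it
qualified iff x < λ.

Assumptions and edge cases:

- **Overlap, not IoU.** Membership uses the raw positive-area predicate,
  not an IoU threshold: a small stem box well inside a large bunch box has
  tiny IoU but is unambiguously a member.
- **A stem overlapping several bunches** is counted once, in the bunch it
  overlaps most (ties to the lowest bunch index). This keeps the member
  counts a partition of the stems (Σx ≤ #stems) and makes the count
  monotone under adding detections. The alternative `all` rule (count in
  every overlapped bunch) is available for sensitivity checks.
- **x = 0 bunches** (a bunch box with no resolved members) are reported
  qualified with a logged warning and an undefined rate, rather than
  raising: a detector can legitimately emit a bunch whose members it
  failed to resolve, and crashing mid-line would be worse than flagging.
- **x = λ is unqualified.** "Fewer than λ" is qualified; at exactly λ the
  rate is 100 % and the ≤ 100 % branch means poor loosening.

Tunables: λ (stems, default 8 — a per-site operator setting), confidence
threshold (default 0.30, the trial's F1-maximizing operating point), and
the multi-overlap rule (default `max_intersection`).

## Regression losses

All losses are per-pair scalars on corner-format boxes; batching and
reduction belong to the training loop. Components (IoU, penalty terms,
focusing coefficient, the enclosing-box normalizer) are returned alongside
the value so a consumer can inspect or detach any part.

- CIoU: `1 − IoU + ρ²/c² + α·v` with the aspect term
  `v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²` and `α = v/((1−IoU)+v)`.
  At pred = gt both numerator and denominator of α vanish; `α·v` is
  defined as its limit, 0.
- WIoU v1: `exp(ρ²/(W_g²+H_g²)) · (1 − IoU)`. The formulation treats the
  enclosing-box normalizer as a constant under differentiation; a scalar
  library has no gradients, so the contract is honored by exposing
  `W_g²+H_g²` among the components for an autodiff consumer to detach.
- WIoU v2 multiplies v1 by the monotonic focusing coefficient
  `(L_IoU / mean(L_IoU))^γ`, where the mean is an exponential moving
  average over observed pairs. The multiplier uses the mean as it stood
  *before* the current pair; the state is updated afterwards. Neither γ
  nor the EMA momentum is a fixed fact of the method — published WIoU
  releases differ — so both are configuration: γ = 1.0 and momentum = 0.01
  by default. The EMA starts at 1.0 (neutral for the first sample) and its
  divisor is floored at 1e-8, since the coefficient is undefined at mean 0.
- Comparators GIoU, DIoU, EIoU and Focal-EIoU (focal exponent 0.5)
  follow their published closed forms and live in a name-addressable
  registry. Note Focal-EIoU's `IoU^γ` weight zeroes the loss at zero
  overlap by construction; the "positive whenever pred ≠ gt" property the
  other losses satisfy does not apply to it there.

All losses are translation- and scale-invariant (every term is a ratio of
matched dimensions), which the property suites verify on randomized pairs.

## Feature-pyramid fusion

Fusion nodes compute `transform(Σ wᵢ·inputᵢ / (Σ wᵢ + ε))` over same-shape
grids, with per-node weights. Raw weights are clamped at 0 (the standard
relaxation of the non-negativity constraint); ε defaults to 1e-4, the
customary fast-normalized-fusion stabilizer, and may be set to 0 in tests
where exact convex combinations are asserted (all-zero weights with ε = 0
raise). The resize contracts default to nearest-neighbor 2× upsampling on
the top-down path and 2×2 average pooling on the bottom-up path, and the
transform defaults to identity — the contribution under test is the
weighted fusion, not the convolution, so the conv hook is injected and
otherwise untouched. Whether pathway weights are shared across nodes is
not constrained; each node takes its own weights.

## Evaluation

Bunch-level classification uses the convention that the *positive* class
is an unqualified bunch — the defect to be caught — which inverts the
intuitive "positive = good". Detected bunches are matched one-to-one to
ground-truth bunch boxes greedily in descending confidence at IoU ≥ 0.5
(the same matcher AP uses). A detected bunch with no match is tallied
against an implicit qualified truth (so a spurious unqualified detection
is a false positive); a missed ground-truth bunch is tallied as implicitly
predicted qualified (so a missed unqualified bunch is a false negative).
This is the only tallying rule under which matched + spurious + missed
totals are conserved in the confusion matrix, and it reproduces the
shipped conveyor-trial tallies exactly.

AP uses all-point interpolation (area under the precision envelope over
every recall increment), not 11-point sampling; mAP averages the two
classes. Zero denominators in precision/recall/F1/accuracy yield 0 by
convention.

The confidence sweep re-runs the entire pipeline at each threshold,
pools the per-scene confusion counts, and reports one row per threshold;
the operating point is the F1-maximizing row.

## Synthetic scenes and the noise model

The generator emulates the acquisition geometry only — 2448×2048-pixel
frames containing axis-aligned stem and bunch boxes — not photometry, and
none of the image-level augmentation a training pipeline would add.
Defaults, chosen once as plausible belt geometry: stems 80–300 px per side
(consistent with small objects occupying roughly 0.05–0.15 of the frame's
normalized extent), bunch boxes 400–800 px, bunch member counts uniform on
a range straddling λ (2–12 in the survey sampler) so both verdicts occur.
Bunch boxes are rejection-sampled pairwise disjoint, member stems are
placed strictly inside their bunch box, and isolated stems keep a 1-px
margin from every bunch, so the ground-truth association is unambiguous
and survives coordinate rounding in text round-trips. Placement attempts
are capped at 1000 per object; a spec too crowded to satisfy raises
rather than looping.

The noise model corrupts truth into simulated detector output: each
object is missed with probability 0.1; surviving corners get independent
Gaussian jitter (σ = 3 px, re-clamped to a valid in-image box);
Poisson(6) spurious boxes are added per scene. Spurious boxes are mostly
stems (15 % bunches), and 70 % of spurious stems are *ghosts* placed
inside a random bunch box, mirroring how detector hallucinations
concentrate in cluttered regions — it is these ghosts that inflate member
counts at permissive thresholds and depress the left flank of the F1
curve. Confidences are drawn from Beta(8, 2) (mean 0.8) for true
detections and Beta(3, 7) (mean 0.3) for spurious ones; these laws are
test fixtures that give the two populations separated confidence ranges,
not measured detector behavior. `conf_true = None` keeps truth
confidences, making the all-zero noise model an exact identity.

What passing synthetic tests shows: the algorithmic pipeline (filtering,
association, rating, tallying, sweeping) is correct and internally
consistent, and the sweep machinery reproduces the qualitative
interior-maximum F1 shape that motivates choosing an operating threshold.
What it does not show: anything about a real detector's accuracy on real
belt imagery — those numbers come from the shipped trial tallies, and
training-side metrics of the detector itself (its mAP on the real
dataset, model size, throughput) are outside this package's reach and
scope.

## Numerical and design choices

- Coordinates are continuous, 0-based, y-down, corner-format internally;
  normalized center-format YOLO labels are converted at the I/O boundary.
  Degenerate (zero/negative-area) boxes are rejected at construction.
- Writers print six decimals; round-trips are exact to 1e-6 in the
  written units.
- The survey problem sizes (100 scenes for recovery and sweeps, 500
  scenes for the association oracle, 1000 pairs for loss invariance) keep
  the full suite and the acceptance script each under a few seconds while
  leaving the checks statistically meaningful.
- Class ids default to stem = 0, bunch = 1 but are configurable (and
  logged at CLI startup), since the id order is a dataset convention.
- Unknown config keys are rejected rather than ignored.

## Known limitations

- No tracking across frames: a bunch seen in consecutive conveyor frames
  is assessed independently each time.
- The association predicate is purely geometric; two separate bunches
  whose boxes overlap the same stem are disambiguated by area, not
  appearance.
- Rotated boxes and masks are out of scope; everything is axis-aligned.
- The synthetic confidence laws are stylized; sweep results on synthetic
  data locate a qualitative, not quantitative, operating point.
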