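# loosenrate

Detection-based quality control for the tobacco-leaf *loosening* stage of
conveyor-belt sorting. Before cured leaves can be graded they must be
spread out so individual leaves separate; bundles that stay clumped
("bunches") slip through grading and have to be caught in real time. An
object detector labels each visible object on the belt either **stem** (a
single exposed leaf stem) or **bunch** (a region of overlapping stems),
and this package turns those boxes into a per-bunch verdict.

## The loosening-rate statistic

For each detected bunch, count the stem detections whose boxes overlap the
bunch box with positive area; call that count *x*. With λ the operator-set
maximum number of stems an acceptably loosened bunch may contain
(default λ = 8), the loosening rate is

    R = λ / x × 100 %

A bunch is **qualified** iff *x* < λ (equivalently R > 100 %); otherwise it
is **unqualified** and the operator is alerted. Detections below a
confidence threshold are discarded first; 0.30 is the default operating
point, the threshold that maximizes bunch-classification F1 in the
conveyor-line trial whose tallies ship with the package
(`loosenrate.datasets`).

Around that core the package provides:

- `loosenrate.geometry` — box arithmetic (IoU, enclosing box, center
  distance) underlying everything else;
- `loosenrate.losses` — the IoU-family regression losses relevant to
  training such a detector (CIoU, WIoU v1/v2 with its monotonic focusing
  mechanism, GIoU, DIoU, EIoU, Focal-EIoU) as inspectable scalar functions;
- `loosenrate.bifpn` — fast-normalized weighted feature-pyramid fusion
  arithmetic with injected resize/transform contracts;
- `loosenrate.evaluation` — greedy IoU matching, precision/recall/F1,
  all-point-interpolated AP and mAP, bunch-level confusion tallies and
  confidence sweeps;
- `loosenrate.synthetic` — a seeded generator of conveyor scenes plus a
  detector-noise model (misses, jitter, ghost detections), so the whole
  pipeline is testable without any image data;
- `loosenrate.io` / `loosenrate.cli` — YOLO label and detection-file I/O
  and the `loosenrate` command-line tool.

## Worked example

A detection file lists one box per line as `x1 y1 x2 y2 conf class`
(pixel corners; class 0 = stem, 1 = bunch). The scene below has one bunch
containing nine confident stem detections, one isolated stem, and one
low-confidence stray:

```sh
$ loosenrate rate --detections dets.txt
bunch 0: x=9 rate=88.9% unqualified
scene: unqualified
```

Nine members exceed λ = 8, so R = 8/9 × 100 % ≈ 88.9 % ≤ 100 % and the
bunch is flagged unqualified; the stray at confidence 0.19 was filtered
out by the 0.30 cutoff before counting. Loss values for any box pair are
available the same way:

```sh
$ loosenrate losses --pred 2,2,4,4 --gt 0,0,2,2
ciou: 1.250000
diou: 1.250000
...
wiou_v1: 1.284025
```

`loosenrate simulate` writes synthetic labelled scenes,
`loosenrate sweep` tabulates TP/TN/FP/FN and F1 across confidence
thresholds, and `loosenrate eval` reports per-class AP and mAP of a
detection file against YOLO labels.

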