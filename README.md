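# olivesort

Pocket classification for olive pitting, slicing and stuffing machines
(DRR machines). The feed chain of a DRR machine carries one olive per
pocket past the punch needles at up to 2500 olives/min; an olive seated
across the pocket (a "boat"), an empty pocket, two olives, or a fragment
all cause pitting faults that mechanical adjustment alone cannot remove.
`olivesort` re-creates, in software, a machine-vision classification stack
built around a hardware-style prototype neural network, so the whole
pipeline — from pocket image to per-batch operating statistics — can be
studied, tested and extended off the machine.

The package is aimed at agri-food machine-vision engineers and at anyone
studying restricted-Coulomb-energy (RCE) prototype classifiers on
low-resolution imagery.

## What is inside

- **`olivesort.rce`** — an emulation of a CM1K-family neuromorphic chip:
  neurons hold a prototype byte vector, a category and an *active
  influence field* (AIF). A neuron fires on a query `v` when
  `d(v, prototype) < AIF` with `d` the L1 (Manhattan) distance. Training is
  incremental: a wrong-category neuron that fires on a labelled example
  shrinks its AIF to that example's distance, and a new neuron is committed
  whenever no same-category neuron fires. Recognition is RBF-style
  winner-takes-all over the firing set (with `identified` / `uncertain` /
  `unknown` statuses) or plain k-nearest-neighbour ignoring the fields.
  Built-in capacity profiles: `cm1k` (1024 neurons × 256 bytes) and
  `curie` (128 neurons × 128 bytes).
- **`olivesort.preprocess`** — ROI crop, Otsu (or fixed) binarization, a
  pixel-area prefilter that diverts *doubles* (≥ 2 components above a
  minimum area) and *small parts* (foreground below a minimum area) before
  the network, and exact box-average downscaling to 16×16 (256 bytes),
  11×11 (121 bytes) or any raster that fits the network profile.
- **`olivesort.labeler`** — moment-based orientation estimation (principal
  axis of the largest foreground component; 0° = correctly seated,
  |angle| ≥ 80° = boat) and the three class schemes: `degrees` (signed 10°
  bins, 18 classes), `intermediate` (normal / intermediate / boat / empty)
  and `simple` (normal / boat / empty).
- **`olivesort.synthetic`** — a deterministic renderer of labelled
  176×144 8-bit pocket scenes (seated/tilted/boat olives between pocket
  walls, empties, doubles, fragments, foreign objects, sensor noise,
  illumination ramp), with per-image child seeds for piecewise
  reproducibility.
- **`olivesort.evaluate`** — the field protocol: training capped at 300
  examples per class, 10 repetitions of 300 random test draws per class
  (3000 presentations per case), per-repetition error rates whose mean is
  the total error, confusion matrices with dedicated unknown/uncertain
  columns, and a resolution-sweep helper.
- **`olivesort.diagnostics`** — per-1000-pocket telemetry: speed
  (pockets/min), production (olives/min excluding empties), category
  percentages, accumulated series, machine-stop flags, and the packet-time
  throughput arithmetic (`1000/ms` images/s).

## Worked example

`examples/03_run_protocol.py` generates a synthetic feed and runs a
scaled-down protocol (100 training examples per class, 5 repetitions of
100 test draws per class):

```
Protocol: scheme=simple network=cm1k resolution=16x16
Committed neurons: 7
Repeatability  Error
            1  0.67%
            2  0.67%
            3  0.67%
            4  0.67%
            5  0.67%
       Totals  0.67%

last repetition confusion matrix (rows=truth):
        normal  boat  empty  unknown  uncertain
normal      95     0      0        4        1
boat         0   100      0        0        0
empty        0     0    100        0        0
```

Seven neurons suffice to sort normal / boat / empty pockets; each
repetition presents 300 pockets and the totals row is the mean error over
repetitions (0.67 %). The unknown/uncertain columns show outcomes where no
neuron fired or firing neurons disagreed; both are resolved by the nearest
prototype and only count as errors when that resolution is wrong.

The other examples cover training and single-image recognition
(`01_train_and_classify.py`), dataset generation with truth-vs-estimated
angles (`02_generate_dataset.py`), and telemetry analytics with stop
detection and a drifting-fault signature (`04_telemetry.py`). A thin CLI
wraps the same API: `olivesort generate`, `olivesort evaluate`,
`olivesort diagnose --log FILE`, `olivesort throughput MS`.

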