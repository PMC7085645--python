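# Methods

## The classifier

`olivesort.rce` implements a restricted-Coulomb-energy (RCE) prototype
network of the kind realised in the CM1K neuromorphic chip family. The
model state is a list of committed neurons, each holding a prototype byte
vector `p`, a category, and an integer *active influence field* (AIF).
All geometry is in the L1 (Manhattan) metric over unsigned bytes, so every
distance, field and decision is integer-exact and the machine is fully
deterministic. The chip family's norm is L1; nothing in the package
depends on the metric beyond `rce.distance`, so swapping it is a one-line
change.

Learning one example `(v, c)`:

1. every firing neuron (`d(v, p) < AIF`) of a category other than `c`
   shrinks its AIF to `max(min_if, d(v, p))` — it will no longer fire on
   `v`;
2. if no neuron of category `c` fires, a new neuron is committed with
   prototype `v` and AIF equal to the distance to the nearest
   different-category prototype, clamped into `[min_if, max_if]` (the
   clamp floor keeps the stored AIF within the declared neuron invariant
   even when an opposite-category prototype lies closer than `min_if`);
3. committing beyond the profile capacity raises an error and leaves the
   model untouched.

Recognition (RBF mode) collects the firing set and applies
winner-takes-all: smallest distance wins, ties broken by commitment order.
A unanimous firing set is `identified`, a disagreeing one `uncertain`
(still reporting the winner), an empty one `unknown`. KNN mode ranks the
k nearest prototypes and ignores influence fields entirely.

**Training to stabilization.** A single pass over a training sequence does
not guarantee consistency: a neuron committed late for category A can
cover an earlier example of category B whose own neuron was shrunk in the
meantime. `RceNetwork.fit` therefore re-presents the training set until a
full pass commits nothing and shrinks nothing (the default; a fixed epoch
count is available). Termination is guaranteed because AIFs are integers
that only decrease and commits are bounded by capacity. At the stable
point no wrong-category neuron fires on any training example, so a trained
example can never be *identified* with the wrong category — at worst it is
`uncertain` when an AIF is pinned at the `min_if` floor. In practice
stabilization takes 2–4 passes on the synthetic datasets.

Defaults `min_if = 2`, `max_if = 16384` follow the chip family's
documented register defaults; both are configurable per profile. The
capacity profiles are `cm1k` (1024 neurons, 256-byte vectors) and `curie`
(128 neurons, 128-byte vectors); a protocol run instantiates the chosen
chip's capacity with the working vector length of its raster (the chip
accepts any vector up to its byte width).

## Image pipeline

A camera frame is nominally 176×144 pixels (25,344 bytes of 8-bit gray).
The default ROI (`x ∈ [28, 148), y ∈ [16, 128)`) spans the pocket interior
of the synthetic scene; real rigs must calibrate their own rectangle via
the config file, and nothing downstream depends on the default.

Feature vectors are exact box averages: output cell = area-weighted mean
of the source pixels it covers, rounded half-up, clipped to [0, 255],
flattened row-major. The operation is the identity on an image already at
the target size, and its integer semantics make hand-computed oracles
exact. Rasters must fit the network profile (16×16 = 256 bytes only on
`cm1k`; 11×11 = 121 bytes on either chip), which is validated at
construction and at config load.

Binarization is Otsu by default with a fixed-threshold override. Otsu
always splits *something*, including pure sensor noise, so the mask is
declared empty when the foreground/background mean separation falls below
`min_contrast` (default 50 gray levels — comfortably above the noise and
illumination-ramp spread of the generator defaults and far below the
olive/background contrast of 170). The prefilter labels a crop `double`
when at least two 8-connected components each reach `component_min_area`
(default 250 px), else `small_part` when nonzero foreground totals under
`small_max_area` (default 500 px), else `pass`. Doubles are tested first:
a pocket holding two substantial fragments is the costlier machine fault.
Area thresholds are configuration, not claims about any particular
machine; the defaults bracket the generator's olive (~1470 px), double
components (~550 px each) and fragments (~130 px).

## Orientation and classes

The labeler binarizes the ROI, takes the largest 8-connected component,
and computes the principal-axis angle from central second moments
(evaluated with y pointing up, so angles are counterclockwise-positive,
in [−90°, 90°]; 0° = seated along the punch axis). Foreground below
`empty_threshold` (1 % of the ROI) is an empty pocket. A component whose
normalised moment anisotropy falls below `1e-3` is reported as 0° with a
degeneracy flag rather than an arbitrary axis. On clean rendered ellipses
the estimator is accurate to well under 1°; the ±3° tolerance used in
closure checks absorbs binarization pixelation under noise.

Class schemes: `degrees` — |angle| in 10° bins, sign kept below 80°, the
[80°, 90°] bin folded into a single `boat` class (16 signed bins + boat +
empty = 18 classes); `intermediate` — normal (|a| < 10°), boat
(|a| ≥ 80°), intermediate otherwise, plus empty; `simple` — normal / boat /
empty only. Published interval lists for such schemes overlap at shared
endpoints; bins here are half-open below, with [80°, 90°] closed, so the
mapping is total and deterministic. The simple scheme rejects
intermediate-range angles by default (they are not part of its universe)
rather than inventing a coercion; an explicit `policy="coerce"` maps them
to the nearer of normal/boat.

## Synthetic scenes

The generator stands in for the machine's camera: LED-lit pockets on a
dark chain. Defaults, chosen once as plausible for such a rig and declared
here rather than claimed faithful to any particular machine: background
30, pocket walls 90, olive 200 (8-bit gray); olive semi-axes 26×18 px
(~1470 px area in a 120×112 ROI); centre jitter ±6 px; Gaussian sensor
noise σ = 8; illumination ramp 0.15 gray/px along X. The scene invariants
(olive/background contrast > 3σ, olive fits between the walls at maximal
jitter) are validated at construction. Doubles are two 16×11 px ellipses
stacked along Y; fragments a single 8×5 px ellipse; anomalies a thin bar
(branch) or small bright disc (stone). One master seed derives a child
seed per image, so any image regenerates independently.

What the generator does **not** emulate: surface texture and specular
highlights, pit-hole shading (available but off by default), motion blur,
perspective, olive-to-olive size variation, and correlated sensor noise.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour on geometrically faithful scenes, not field performance on real
fruit; the published field error rates for this class of system were
measured on a real 10,000-image set that has no public accession.

## Evaluation protocol

A protocol run prefilters and vectorizes every sample once, shuffles each
class pool with the run seed, trains a fresh network (stabilized fit) on
up to `train_cap` (default 300) samples per class, and uses the remainder
as the test pool — falling back to the training pool, flagged, when
nothing remains. Each of `reps` (default 10) repetitions draws
`test_per_case` (default 300) samples per class, with replacement if the
pool is smaller (flagged). The total error is the arithmetic mean of the
per-repetition error rates. Prefilter-diverted samples never reach the
network and are tallied separately. `uncertain` outcomes resolve by
winner-takes-all and `unknown` outcomes by the nearest prototype (the
chip's KNN fallback); either counts as an error only when the resolved
category is wrong, and both keep dedicated confusion-matrix columns so the
resolution is auditable.

Problem sizes used by the shipped checks: the simple-scheme protocol runs
at full sizing (600 generated per class; 300 train, 10 × 300 test); the
resolution sweep runs 10 seeds × 3 rasters at 240 per class (120 train,
3 × 120 test) — sizes chosen so the whole suite stays comfortably
interactive on one CPU.

## Known limitations

- The resolution effect (16×16 ≤ 11×11 ≤ 10×10 mean error) is real but
  small on these synthetic scenes — a few tenths of a percentage point,
  comparable to seed-to-seed variation. Box-average grayscale features
  preserve sub-cell coverage fractions, so the olive's edge geometry
  survives coarse rasters; on real textured imagery the penalty for low
  resolution is larger. Under other seed batches individual links of the
  chain can invert.
- The committed-neuron counts reported by the protocol are observed
  outcomes of the training dynamics, not budgets; they depend on class
  separability and training order.
- The simple scheme's ~0 % synthetic error reflects the generator's clean
  class geometry; it is the qualitative counterpart of a sub-1 % field
  error, not a reproduction of it.
- Telemetry stop detection is a threshold on inter-batch gaps (default 5×
  the median); it flags stops, it does not classify their causes.
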