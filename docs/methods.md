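# Methods

## Problem and scope

`tonguegeom` analyses *segmented* tongue images: binary masks in which
foreground pixels mark the tongue region of a standardized frontal
photograph (tip toward the bottom of the image, root toward the top).
Segmentation and color correction are upstream concerns and out of
scope here. From each mask the package computes 13 geometry features,
assigns one of five canonical tongue shapes used in traditional Chinese
medicine (TCM) diagnosis — rectangle, acute triangle, obtuse triangle,
square, circle — with a fixed threshold decision tree ("coarse level"),
and discriminates two patient groups that share a shape using a selected
feature subset and a linear maximum-margin classifier ("fine level").

## The 13 geometry features

With `x_min, x_max, y_min, y_max` the bounding-box coordinates of the
foreground (0-based pixels, y downward):

| # | name | definition | units |
|---|------|------------|-------|
| 1 | `w`   | width, `x_max − x_min + 1` | px |
| 2 | `l`   | length, `y_max − y_min + 1` | px |
| 3 | `lw`  | `l / w` | – |
| 4 | `z`   | smaller half distance, `min(l, w) / 2` | px |
| 5 | `cd`  | center distance, `\|(Ymax(x_max)+Ymax(x_min))/2 − y_cp\|` | px |
| 6 | `cdr` | `cd / l` | – |
| 7 | `a`   | foreground pixel count | px² |
| 8 | `ca`  | inscribed-circle area, `π z²` | px² |
| 9 | `car` | `ca / a` | – |
| 10 | `sa` | inscribed-square area, `4 z²` | px² |
| 11 | `sar` | `sa / a` | – |
| 12 | `ta` | triangle area (shoelace) over the extreme points | px² |
| 13 | `tar` | `ta / a` | – |

`y_cp = (y_max + y_min)/2` is the vertical bounding-box center and
`Ymax(c)` the bottom-most foreground row in column `c`. The triangle of
feature 12 has vertices `L = (x_min, Ymax(x_min))`,
`R = (x_max, Ymax(x_max))` and `B = (Xmed(y_max), y_max)`, with
`Xmed` the lower median of the foreground columns in the bottom row.

Numerical choices:

* **Pixel-extent convention.** `w` and `l` are `max − min + 1`, so an
  N-pixel run has length N and a fully filled W×H box satisfies
  `a = l·w` exactly. This makes the rectangularity ratio `a/(l·w)`
  attain its theoretical maximum of 1 on filled rectangles and keeps
  `sar = 1` exact for filled squares of any side; the literal
  `max − min` difference would overshoot both identities by one pixel
  per axis. The discrepancy vanishes at image scale.
* **`cd` as an absolute value.** The quantity is a distance; the signed
  vertical offset (positive = extreme-column bottoms below center) is
  available via `center_distance(..., signed=True)` as a diagnostic.
* **Tie-breaks.** The bottom-vertex column uses the *lower* median on
  even counts, a deterministic choice.
* **Degenerate masks.** Single-pixel and single-row/column masks yield
  finite features: `z = 0.5 > 0` and `l, w ≥ 1` guarantee no division
  by zero. `a` is stored as an exact integer; everything else in double
  precision.

## Coarse level: the shape decision tree

The first split routes near-unity aspect ratios
(`0.95 ≤ lw ≤ 1.05`, both ends inclusive) to the square/circle branch.
There, with the average radius `r_avg = (l + w)/4`, the statistic
`T_sc = a / r_avg²` equals 4 for a filled square and tends to π for a
disk; the cut is `square ⇔ T_sc ≥ π + ε` with `ε = 0.1` (π at full
floating-point precision, since the comparison is symbolic in π).
Otherwise the rectangularity `T_rao = a/(l·w)` decides
`rectangle ⇔ T_rao ≥ 0.85`; remaining masks are
`acute_triangle ⇔ lw ≥ 1.05`, else `obtuse_triangle`. (A filled triangle
has `T_rao ≈ 0.5`, far below the rectangle cut.) Because the lw band is
inclusive at 1.05, the acute test is only ever met strictly.

All five thresholds were chosen empirically for clinical tongue masks
and are exposed as a `Thresholds` config object (and CLI flags) rather
than constants. Every finite feature vector receives exactly one label.

## Fine level: SFS with a linear margin classifier

Two classes sharing a coarse shape are separated as follows:

1. **Split.** One stratified half split per run: per class, ⌊n/2⌋
   samples train, the rest test, drawn uniformly under the run seed.
2. **Criterion.** `J` = *average accuracy*, the macro average of
   per-class recall on the test half. The clinical class pairs this
   protocol targets are strongly imbalanced (hundreds vs tens of
   samples), where plain accuracy is dominated by the majority class;
   plain accuracy remains available via `ClassifierConfig(average="plain")`.
3. **Classifier.** A support-vector machine with the linear (dot
   product) kernel, regularization `C = 1` by default. Selected
   features are z-scored with training-fold statistics first — the raw
   scales span unit ratios to 10⁴ px² areas, which would otherwise
   dominate a dot-product kernel. A constant training feature falls
   back to unit deviation instead of failing.
4. **Search.** Sequential forward selection from the empty set: each
   step adds the feature maximizing `J` on the *same* fixed split (no
   nested resampling — the simplest faithful reading of the protocol),
   ties broken toward the lowest feature index, terminating when all 13
   features are in. The report contains the full addition order, the
   criterion path, and the best (earliest on ties) prefix with its `J`.

An optional repeat mode (`--repeats k`) reruns the protocol with
incremented seeds and reports mean ± sd of `best_J`.

## Synthetic shape generator

The clinical dataset behind this design (672 images, 8 diagnostic
groups) is private, so the package ships a generator that rasterizes
the five canonical shapes plus a tongue-like tapered superellipse
(`tongue_blob`). Rasterization is center-of-pixel inclusion, exact for
axis-aligned rectangles; triangles are apex-down to match tongue
orientation. Controls:

* `width_px`, `height_px` — target extents (≥ 8 px). Spec validation
  enforces the aspect constraints of each family (square: equal
  extents; rectangle: ratio outside [0.95, 1.05]; acute/obtuse
  triangle: ratio above 1.05 / below 0.95) so a generated mask's
  nominal shape is attainable by the tree.
* `noise` ∈ [0, 0.2] — amplitude of a smooth radial boundary
  perturbation built from 4 low-order harmonics (wavenumbers 2–5) with
  seed-drawn amplitudes and phases. Tongue contours are smooth, so this
  models realistic segmentation/shape variability better than per-pixel
  salt noise.
* `rotation_deg` ∈ [−10, 10] — small in-plane rotation, as tongue
  photographs are approximately upright.
* `seed` — full determinism.

`generate_cohort` draws two-class samples by jittering a template's
overall scale by ±10% per sample (one factor for both axes, so the
aspect ratio — and hence the shape family — is preserved by
construction) with fresh per-sample noise seeds, and returns extracted
features with labels and the masks themselves.

What the generator does *not* emulate: real segmentation artifacts
(holes, ragged borders, attached lips), asymmetric tongues, and the
class-conditional geometry distributions of actual patient groups.
Passing tests therefore establish correctness of the *computations* and
the self-consistency of the decision rules on ideal-to-mildly-perturbed
shapes — not clinical accuracy, which requires the private images.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on desk-scale inputs
chosen to exercise every code path while staying analytic: anchor masks
of 300–600 px extent (where `T_sc` of a filled square is exactly 4,
`T_rao` of a filled rectangle exactly 1, and a disk's `T_sc` is within
1% of π); 100 noise-free masks per shape at 100–400 px for the coarse
check; 250 random small masks for the feature invariants; and a
100-sample circle-vs-square cohort (noise 0.02) for the fine-level
recovery and its 20-seed permutation null.

## Known limitations

* The decision tree is a fixed-threshold rule set tuned for clinical
  masks; heavily rotated or concave masks can fall outside the intended
  shape families (e.g. a rotated rectangle's bounding box dilutes
  `T_rao` below the rectangle cut).
* `cd`/`ta` depend only on the extreme columns and bottom row, so they
  are sensitive to single-pixel protrusions at the mask border.
* The fine level is strictly pairwise; multi-class runs are out of
  scope.
* Whether "average accuracy" in the original protocol is macro or plain
  is not documented; this package defaults to macro (see above) and
  exposes both.
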