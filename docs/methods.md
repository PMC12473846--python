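# Methods

This note records the models implemented by `wildtherm`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical conventions used throughout.

## Image model and conventions

Frames are 8-bit grayscale `numpy.uint8` arrays indexed `(row, col)` with the
origin at the top-left; bounding boxes are half-open `(r0, c0, r1, c1)`.
All windowed operators replicate edge pixels at the border: a zero-padded
border would read as a cold-to-warm step and synthesize edges that are not in
the scene. Intermediate arithmetic is floating point; results are rounded
half-up (`floor(x + 0.5)`) back to 8-bit, so ties never depend on banker's
rounding.

The ROI is a simple polygon in pixel coordinates; a pixel belongs to the ROI
when its center is inside or on the polygon boundary. Cropping keeps the
polygon's tight bounding box and sets out-of-polygon pixels to 0 — the
coldest value — so masked-out road and sky can never masquerade as a warm
body downstream. A polygon generalizes the horizontal/vertical/diagonal
separating lines a deployment would actually configure.

## Operators

**Bilateral filter.** Defaults σ_s = σ_r = 75 with a 9×9 neighborhood. The
neighborhood "distance 9" is taken as the full diameter; a 5×5 window
remains reachable through `filters.bilateral_diameter`. With σ_r of this
magnitude the range kernel only suppresses neighbors differing by well over
a hundred intensity units, which is exactly the animal-to-ground contrast in
thermal imagery — the filter smooths the meadow while leaving warm-blob
edges sharp.

**Global threshold.** Strict inequality: a pixel equal to the threshold maps
to 0. Defaults: threshold 180, I_max 255.

**Gaussian blur.** The default mask is the normalized 3×3 binomial kernel
(1/16)·[[1,2,1],[2,4,2],[1,2,1]] (k = 1). Kernel validation requires
non-negative weights summing to 1 within 1e-12 and symmetry under 90°
rotation, so convolution and correlation coincide.

**Sobel / Canny.** Gradient direction is quantized to {0°, 45°, 90°, 135°}
modulo 180°, ties toward the smaller label. Non-maximum suppression keeps
ties (`>=` against both neighbors along the gradient) so plateau maxima are
thinned rather than erased; out-of-bounds neighbors count as magnitude 0.
Hysteresis uses 8-connectivity — "in contact" is read as any adjacency —
implemented as connected-component labeling of the strong∪weak mask keeping
components that contain a strong pixel, which is equivalent to flood fill
from strong seeds (and is tested against one). The double thresholds are not
dictated by the method description; defaults 50/100 on the raw Sobel
magnitude scale follow the conventional 1:2 ratio and are config-exposed.
Magnitudes stay real-valued until hysteresis binarizes.

**k-means quantization.** One-dimensional Lloyd iteration, k = 2, at most
200 iterations, stopping when no center moves more than ε = 0.5 intensity
units. Centers initialize as k distinct pixel values drawn uniformly with a
configured seed (default 0); assignment ties go to the lower-indexed center;
an empty cluster is re-seeded on the pixel value farthest from its center.
Each frame is quantized independently. The per-iteration within-cluster sum
of squares is recorded so monotonicity is assertable.

**Dilation.** Flat square structuring element (default 5×5), i.e. a
sliding-window maximum — the supremum form of grayscale dilation specialized
to a uniform kernel.

**Contours.** One outer contour per 8-connected white component, traced by
Moore-neighbor border following (clockwise, Jacob's stopping criterion);
holes are ignored, since the decision stage only needs each object's extent.
Straight horizontal/vertical/diagonal runs compress to endpoints, losslessly
(`Contour.expand` reproduces the trace). Components touching row/col 0 or
max are flagged and rejected before the animal decision: such objects are
partially outside the field of view. They remain available, flagged, to the
boundary-event classifier — this reconciles edge rejection with reasoning
about animals entering or leaving the frame.

**Features and matching.** The built-in detector is a compact
scale-invariant feature pipeline: per-octave Gaussian stacks (σ0 = 1.6,
3 intervals, up to 3 octaves as region size allows) with a 2×-upsampled
first octave — without it, blobs only a few pixels across peak below the
base scale and produce no interior scale-space extremum; 3×3×3
difference-of-Gaussian extrema; contrast threshold 0.03 (on [0, 1] scale)
and Hessian edge-ratio rejection (r = 10); a 36-bin dominant-orientation
histogram; and a 4×4×8 orientation-histogram descriptor, L2-normalized with
the standard 0.2 clamp. Matching is exhaustive nearest-neighbor search under
Euclidean distance with Lowe's ratio test (default 0.75); an exact
(distance-0) match or a missing second neighbor always qualifies, so a
region literally equal to a chip self-matches in full.

A frame is declared positive when some interior contour of area ≥ 9 px
reaches 4 good matches against some chip. Regions under 64 px return an
empty feature set (with a warning, not an error): no descriptor exists at
that size. For exactly that regime — the 1–3 px targets a thermal camera
sees at hundreds of meters — the decision stage offers an area-only
candidate rule (`match.fallback_area`). It is **off** by default, keeping
the decision purely feature-based; the synthetic benchmark configuration
turns it on, because its few-pixel targets are below any descriptor scale by
construction.

**Motion threshold.** The motion pipeline reuses the global thresholding
step on the dilated difference image. A threshold of 180 is meaningful for
raw thermal frames but suppresses virtually any inter-frame difference, so
the motion stage defaults to 25 (`motion.threshold`); the single-frame value
remains reachable there.

## Evaluation

Per-frame presence classification only; boxes are carried for inspection and
used in tests (IoU), never as a headline metric. Percentages are reported to
two decimals, with the exact rationals retained alongside. A zero
denominator reports as undefined (`None`), never 0. A motion run's first
frame has no predecessor: it is emitted with `scored=False` and excluded
from the confusion counts, so the motion method scores N−1 frames.

Reported wall-clock timing is measured with a monotonic clock around each
frame's full pipeline. Because timing is inherently non-reproducible, the
CLI omits it from results and report files unless `--timing` is passed;
default runs under a fixed seed are therefore byte-identical across
invocations.

## Synthetic scenes

The generator emulates the cropped roadside view of a low-resolution thermal
camera: 219×134 px frames, a vertical background gradient from 20 (cool sky
side) to 90 (warmer ground), additive Gaussian sensor noise (σ = 3, clipped
to [0, 255]), static warm distractors, and animals as hard-edged rasterized
ellipses at intensity 230 — no antialiasing, so contour areas and footprints
are exactly enumerable. Distractors and animals are painted onto the
background before noise is added. A configuration is rejected unless every
animal exceeds the background maximum by a detectability floor (40 by
default) and is visible in at least one active frame. Ground truth marks
per-frame presence and bounding boxes; each animal also yields a noise-free
template chip for the reference library.

The default benchmark scene (seed 42) holds one 7×5-px animal moving
1 px/frame during frames 20–60, a 200-intensity building rectangle touching
the top frame edge — so the border-rejection rule removes it from every
single-frame decision, as ROI cropping would in the field — and an interior
water-reflection ellipse at 170 flickering ±10 units, which exercises
single-frame false positives while staying below the motion threshold. The
dataset-composition bundle reuses this scene family at the shapes
(89 total / 80 with animals), (84/8), (84/4) and (17/13), plus a
stationary-animal twin of the long-presence scenario: frame differencing
sees a motionless animal only when it appears, so its sensitivity collapses
there — the long-presence failure mode of motion detection.

What the generator does **not** model: physically based radiance, weather
(fog, rain, snow), animal gait or shape change, sensor fixed-pattern noise,
and rolling shutter. Passing benchmarks therefore demonstrate the relative
behavior of the pipelines under controlled contrast and motion, not absolute
field performance; on the benign synthetic scene several methods saturate at
100% sensitivity, which real footage would not produce.

## Problem sizes

The shipped benchmark uses 100-frame sequences at 219×134 px and the test
suite keeps oracle comparisons on ≤ 32×32 random images (50 per operator),
sizes at which the naive nested-loop oracles stay fast while covering every
border and tie case.

## Known limitations

- The feature detector is a faithful but compact implementation; it has no
  subpixel keypoint refinement and a single dominant orientation per
  keypoint, so its match counts are conservative compared to full SIFT.
- Matching operates on the contour's bounding box of the original grayscale
  frame; heavily fragmented binary maps (Canny rings) yield boxes smaller
  than the object, which is why the benchmark relies on the area rule for
  few-pixel targets.
- `quantized_to_binary` supports exactly k = 2; larger k would need a
  mapping policy for intermediate clusters.
- ROI polygons must be supplied per deployment; no automatic scene
  segmentation is attempted.
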