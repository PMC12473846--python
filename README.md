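# wildtherm

Classical image-processing pipelines for detecting wild animals in roadside
thermal camera footage, built for wildlife–vehicle collision (WVC) warning
systems. A low-resolution thermal camera watching a roadside meadow renders a
moose or deer as a warm blob of only a few pixels; the task is to decide, per
frame, whether an animal is present, quickly enough for an embedded warning
node. `wildtherm` implements four classical detection methods end to end,
together with region-of-interest (ROI) preprocessing, a contour/feature
matching decision stage, an evaluation harness, and a seeded synthetic
thermal-scene generator so everything is testable with no field data.

## The methods

Each pipeline turns an 8-bit grayscale frame into a binary image, extracts
contours of the white components, rejects contours that intersect the frame
edge, and decides animal presence by matching each remaining contour region
against a library of reference animal chips.

1. **Bilateral filter + threshold.** Edge-preserving smoothing

   I'(x) = (1/W_p) Σ_{x_i ∈ Ω} I(x_i) · f_r(|I(x_i) − I(x)|) · f_s(‖x_i − x‖)

   with Gaussian spatial and range kernels (σ_s = σ_r = 75, 9×9
   neighborhood), followed by global binarization
   I_proc = I_max if I > threshold else 0 (threshold 180, strict inequality).

2. **Gaussian blur + Canny.** 3×3 binomial blur (1/16·[[1,2,1],[2,4,2],[1,2,1]]),
   Sobel gradients G = √(G_x²+G_y²), θ = atan2(G_y, G_x) quantized to
   {0°, 45°, 90°, 135°}, non-maximum suppression along the gradient, and
   double-threshold hysteresis with 8-connected weak-to-strong linking.

3. **Nearest-average (k-means) quantization.** Pixel intensities are
   clustered into k = 2 groups by Lloyd iteration (≤ 200 iterations,
   stop when centers move ≤ 0.5); the brighter cluster maps to white, since
   thermal imagery renders warm bodies as the lightest shades.

4. **Inter-frame motion.** Both frames are blurred, the per-pixel absolute
   difference |P_prev − P_curr| is dilated with a flat 5×5 structuring
   element (sliding-window maximum) and thresholded; moving objects produce
   white regions, static warm distractors cancel exactly.

Detection quality is scored per frame against ground truth:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/(TP+TN+FP+FN), plus mean per-frame execution time.

## Worked example

Generate the default synthetic benchmark (100 frames of 219×134 px, one
7×5-px animal at intensity 230 crossing the meadow during frames 20–60, a
warm building touching the frame edge, a flickering water reflection) and
compare all four methods. The tiny targets carry no usable keypoints, so the
benchmark config enables the area-based candidate rule:

```sh
wildtherm simulate --out scene --seed 42
printf 'match:\n  fallback_area: 9\n' > bench.yaml
wildtherm compare scene --truth scene/truth.csv --config bench.yaml --out rep
```

which prints

```
   method  sensitivity_pct  specificity_pct  accuracy_pct  n_frames
bilateral            100.0           100.00        100.00       100
    canny            100.0             0.00         41.00       100
 quantize            100.0             0.00         41.00       100
   motion            100.0            98.28         98.99        99
```

All four methods see the animal on every active frame of this benign scene.
The interesting column is specificity: Canny and the quantizer flag the
static water reflection in every frame (a classic single-frame false
positive), while the motion method cancels static content exactly — its only
false positive is the frame where the animal leaves the scene. The bilateral
pipeline survives here because the reflection (intensity 170) sits below the
180 threshold. The motion method scores 99 frames because the first frame
has no predecessor.

`wildtherm detect` runs a single method and writes per-frame results
(including ENTERED/EXITING/PRESENT/ABSENT boundary events), and
`wildtherm evaluate` scores any externally produced results CSV against a
truth table. Per-frame wall-clock timing is off by default so repeated runs
are byte-identical; pass `--timing` to measure it.

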