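# Methods

## The measurement problem

A feeding hawkmoth drains an artificial flower (a 1 mL syringe body with a
funnel cap) while a camera films the scene laterally at 10 frames/s against
back-illumination. Two landmarks are tracked per frame: the nectar meniscus
(whose descent encodes ingested volume) and the proboscis tip (whose depth
below the meniscus is the submergence). The pipeline converts an image
sequence into a calibrated drinking-rate series in mL/s and a submergence
series in mm, then reduces each recording to medians for cross-recording
statistics. Image rows grow downward, so a falling nectar level means an
increasing meniscus row and a positive drinking rate.

## Synthetic scenes and what they do (and do not) emulate

`nectartrack.scene` renders idealized geometry: a bright background
(backlit diffuser), a rectangular tube with dark walls, straight horizontal
graduations, a translucent nectar column (grey 150 of 255) beneath a darker
meniscus band, a jointed dark proboscis polyline ending at the configured
tip, optional darkened shadow bands hugging the tube walls, and additive
Gaussian sensor noise (default sigma 2 grey levels). Default grey levels
(background 230, walls 30, markings 60, meniscus 70, proboscis 45) were
chosen once as plausible for a high-contrast backlit near-IR scene; no
published intensity measurements of such rigs exist, so these are free
parameters of the generator. Rendering is bit-deterministic given
(config, seed): frame i uses `default_rng([seed, i])`.

What the generator does **not** model: lens blur and defocus, wing or body
occlusion of the tube, flicker, proboscis curvature changing within a
recording, meniscus curvature (rendered as a flat band), or fluid dynamics.
Passing tests therefore demonstrate that the measurement chain is correct
and well-calibrated on scenes it fully understands, not that the trained
networks would transfer to real footage.

Ground truth carries the analytic meniscus trajectory and its derivative;
for linear trajectories (`LinearLevel`) the derivative is exact, otherwise
a central difference with h = 1e-4 s is used. True volume rate =
(rows/s) × ml_per_pixel through the same marker calibration the pipeline
uses, so ground truth and measurement share one volume scale.

A proportional reduced-resolution mode (`SceneConfig.scaled(f)`) shrinks
all geometry; the test suite and the acceptance script run localization at
f = 0.5 (300×400 frames, 50-column crops) so the whole suite fits a single
CPU in minutes. These problem sizes (80 labeled frames, 64 train / 16
held out, 18 epochs; 50-recording rate cohorts; 20-seed calibration loops)
are the package's chosen study conditions.

## ROI cropping

Horizontal Sobel gradient → absolute magnitude → Li minimum-cross-entropy
threshold → binary mask → column sums. The tube's graduations make its
columns the densest in horizontal edges; the frame is cropped to the 100
columns centred on the argmax (ties broken to the lowest column index;
windows near the border are shifted inward to preserve the fixed width,
since the network input size is fixed). The window is computed once per
recording from the first frame — the flower is stationary on its stage —
with per-frame recomputation available via the pipeline configuration.

The Li threshold is computed by exact minimisation of the cross-entropy
criterion −(S_b ln μ_b + S_a ln μ_a) over the midpoints between consecutive
distinct values. The classical fixed-point iteration started from the
sample mean can converge to a spurious low threshold when a huge near-zero
background mode (sensor noise) dwarfs the edge signal — on synthetic frames
this put the threshold inside the noise and destroyed the column signal.
The global minimiser is itself a fixed point of Li's update and is scale
equivariant (threshold(k·v) = k·threshold(v)); tests verify it against a
brute-force scan of the criterion.

Edge density is flat across the tube interior (every interior column
crosses the same graduations), so the argmax lands anywhere inside the
tube, not at its exact centre. The default tube width (40 px) is chosen so
the 100-column window always contains the whole tube even at worst-case
tie-breaks.

## Localization networks

Both landmarks use the same architecture: a U-net emitting a per-pixel
probability map the size of its input. Because no deep-learning framework
is part of this package's dependency set, the U-net is implemented directly
in NumPy (`nectartrack.unet`): 3×3 im2col convolutions with ReLU, 2×2 max
pooling, nearest-neighbour upsampling, per-level optional skip
concatenation, a 1×1 output convolution, hand-written backpropagation
(verified against numerical gradients in float64), and Adam with decoupled
weight decay (default 0.0005). Inputs of any size are edge-padded to a
multiple of 2^depth and outputs cropped back. Architecture is a
configuration surface (`UNetSpec`): depth, per-level filters, per-level
skips. The library default is depth 3 / filters (16, 32, 64); tests and the
acceptance script use depth 2 / (8, 16), which trains in ~2 min on one CPU
(18 epochs; fewer epochs leave held-out IoU seed-dependent).

Training minimises per-pixel binary cross-entropy with a positive-class
weight (neg/pos frequency ratio, capped at 40) to counter the extreme
imbalance of thin-object masks. Augmentation is restricted to
label-geometry-preserving transforms applied to frame and mask alike:
horizontal flips, integer translations up to ±4 px, brightness/contrast
jitter, additive Gaussian noise (image only). Training is fully
deterministic under a seed.

Mask → measurement rules: threshold 0.5; meniscus = centroid of the
largest connected component; proboscis tip = bottom-most pixel (column
midpoint on ties) of the component whose bounding-box bottom edge lies
lowest — shadow fragments near the tube walls cannot steal the selection
unless they reach deeper than the true tip. Ties between equal candidates
resolve to the lowest label index, making both selectors pure functions of
the mask. IoU of two empty masks is defined as 0 and such frames are
excluded from performance summaries.

At the reduced training scale the meniscus network is accurate (held-out
median IoU ≈ 0.57–0.74 across seeds, row error ≤ 3 px on ~100 % of
frames). The proboscis
tip is a much sparser and locally ambiguous target (the disk label covers
~0.2 % of pixels, and "end of a thin line" needs longer-range context);
with the same short schedule its IoU stays low. The pipeline trains and
applies both networks, but quantitative claims at this scale are made for
the meniscus only, and the ground-truth bypass keeps the kinetics and
statistics stages independent of training quality.

Outlier rejection: an isolation forest (100 trees, contamination 0.05,
seeded) over per-frame features (centroid row, column, region area,
frame-to-frame row displacement) — capturing both spatially odd detections
and sudden jumps. Flags apply to meniscus measurements only; with fewer
than 10 measurements filtering is skipped with a warning.

## Drinking rate and submergence

LOESS with frac = 0.5, degree = 1 by default: at each point a local
polynomial is fit by weighted least squares to the nearest ⌈frac·n⌉ points
in time (12 of 24, matching the reference configuration at n = 24; the
⌈frac·n⌉ rule generalises it to other recording lengths). Weights are
Gaussian in distance with the bandwidth set so the farthest included
neighbour has weight exp(−1/2) — a concrete, testable convention, exposed
as `bandwidth_scale`. The rate is the analytic first-derivative coefficient
of each local polynomial (exact for the local model and well-defined at the
endpoints), not a finite difference of fitted values. Duplicate time stamps
are averaged before fitting; a neighbourhood with all-identical times
raises an error naming the time point. Degree-1 fits reproduce affine data
to machine precision for any frac; slopes scale exactly with the data.
Alternate parameter sets (frac 0.9 / 0.2, degree 2) are runnable through
`LoessParams` for sensitivity checks.

Calibration: ml_per_pixel is the absolute least-squares slope of marked
volume against marker row. mm_per_pixel multiplies it by the syringe
barrel's physical length per millilitre (default 58 mm/mL for a 1 mL
syringe) — the marker geometry itself fixes the millimetre scale, since no
separate scale reference exists in such scenes. Rates below −1e−12 mL/s are
flagged invalid (fluid leaving the proboscis is implausible) and excluded
from summaries; the tolerance absorbs ±1e−17 slopes from numerically flat
fits. Submergence = (tip row − meniscus row) × mm_per_pixel; frames missing
either landmark are skipped and negative depths (tip above the fluid) are
not retained, with 0 mm inclusive.

LOESS edge effects make the integral of the rate series differ from the
calibrated start-to-end displacement by a few percent on curved
trajectories (tested at 5 %); on linear trajectories the match is exact.

## Statistics

Per-recording summaries take medians over valid/retained rows only; total
volume is Σ rate·Δt over valid rows; a recording with no valid rows is
marked unusable. Mann-Whitney U uses exact enumeration when both groups
have ≤ 8 tie-free observations and the tie-corrected normal approximation
otherwise; the exact branch is verified against full permutation
enumeration for all group sizes ≤ 6. Regressions are ordinary least
squares with Pearson R, the two-sided slope t-test on n−2 df (identical to
the test on R), and a 95 % confidence band for the mean response verified
against statsmodels. No multiple-testing correction is applied — tests are
reported individually. The evaporation bound is rate × duration / 86400 in
mL: at the literature maximum of 200 µL/day, a 600 s recording loses at
most ≈ 1.4×10⁻³ mL, so ingestion is the only non-negligible volume sink.

The synthetic submergence-rate study (`simulate_study`) draws per-recording
true rates log-uniform in [5×10⁻⁴, 5×10⁻³] mL/s and submergence depths
uniform in [2, 25] mm, independently (effect size 0) or with a linear
dependence (mL/s per mm). Tracks are ground-truth trajectories with 2 px
row noise pushed through the same LOESS estimation as real tracks. With no
true effect the regression rejects at ≈ the nominal 5 % across seeds; with
a strong effect (10⁻⁴ mL/s per mm against a narrow base-rate spread) it
rejects in ≥ 90 % of seeds. The ≤ 10 mm restricted regression mirrors the
shallow-submergence sensitivity check.

The volume-vs-mass validation mechanism is simulated directly: video
captures a uniform 40–90 % of each day's intake, so measured volume never
exceeds the balance's mass change and the regression slope is below 1.

## Pipeline

`run_pipeline` executes simulate → crop → (train) → track → rate → analyze,
each stage reading only the declared outputs of its predecessors and
writing a manifest entry (parameters, SHA-256 of outputs, package version).
Reruns with the same configuration reproduce identical CSV checksums. The
tracker stage applies the trained networks or, by default, the ground-truth
bypass with configurable injected noise. Frames are exchanged as PNG
sequences; proprietary camera containers are out of scope.

## Known limitations

- Synthetic scenes are idealized (see above); localization accuracy numbers
  do not transfer to real footage without retraining on real labels.
- Proboscis-tip localization is under-trained at the CI-scale schedule.
- The NumPy U-net is CPU-bound and meant for small inputs; it is not a
  general-purpose training framework.
- LOESS neighbourhoods are defined in time, so long gaps (sparse
  measurement regions) can leave local fits poorly conditioned; monotone or
  k-NN regression alternatives are deliberately out of scope.
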