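# nectartrack

Video-based measurement of nectar feeding in hawkmoths (*Manduca sexta*).

Hawkmoths drink nectar through a proboscis often longer than their body,
usually while hovering. A standard way to measure how fast they drink is to
film an artificial flower — a 1 mL syringe body lit from behind — and watch
the nectar meniscus descend. This package implements that measurement chain
end to end, together with a synthetic-scene generator that renders the same
kind of footage with exact ground truth, so every stage can be verified
against known answers:

1. **ROI cropping** (`nectartrack.crop`) — the syringe's horizontal volume
   graduations make its pixel column the densest in horizontal edges;
   a horizontal Sobel filter, a Li minimum-cross-entropy threshold and
   column sums locate it, and each 600×800 frame is cropped to the 100
   columns around the peak.
2. **Localization** (`nectartrack.localize`, `nectartrack.unet`) — two small
   U-nets (NumPy implementation, im2col convolutions, Adam with decoupled
   weight decay 0.0005) produce per-pixel probability maps for the nectar
   meniscus and the proboscis tip. Maps are thresholded at 0.5; the largest
   connected component is the meniscus (centroid recorded), and the
   component whose bounding box reaches lowest in the image holds the
   proboscis tip. An isolation forest flags implausible meniscus
   measurements.
3. **Kinetics** (`nectartrack.kinetics`) — meniscus tracks are smoothed with
   LOESS (default frac = 0.5, degree = 1, Gaussian distance weights; each
   local fit uses the nearest ⌈frac·n⌉ points, e.g. 12 of 24). The drinking
   rate is the analytic slope of each local polynomial converted to mL/s by
   a per-recording calibration fit to the syringe volume markers; negative
   rates are flagged implausible. Submergence depth is
   (tip row − meniscus row) in mm, with negative depths discarded.
4. **Statistics** (`nectartrack.stats`) — per-recording summaries (median
   rate, median submergence, total volume), Mann-Whitney U comparisons
   between behavior groups, OLS regressions of median rate on median
   submergence (full and ≤ 10 mm), a volume-vs-mass validation regression,
   and the evaporation bound (200 µL/day over 600 s ≈ 1.4×10⁻³ mL,
   negligible).
5. **Pipeline** (`nectartrack.pipeline`, CLI `nectartrack`) — runs
   simulate → crop → train → track → rate → analyze with a manifest of
   parameters and output checksums; the tracker can be bypassed with the
   simulator's ground truth to decouple kinetics from network training.

## Worked example

```python
import numpy as np
from nectartrack.scene import SceneConfig, LinearLevel, render_recording
from nectartrack.crop import crop_to_roi
from nectartrack.localize import track_from_ground_truth
from nectartrack.kinetics import rate_series

cfg = SceneConfig(duration=20.0, nectar_level_fn=LinearLevel(150.0, 1.0))
rec, gt = render_recording(cfg)            # 200 frames, 600x800, 10 FPS
cropped, window = crop_to_roi(rec.frames[0])
print(cropped.shape, window.center_col)    # (600, 100) 382

cal = cfg.calibration()
track = track_from_ground_truth(gt, row_noise_sigma=2.0, seed=1)
rates = rate_series(track, cal)
print(round(float(gt.rate_ml_s[0]), 6))                             # 0.00202
print(round(float(rates.loc[rates.valid, "rate_ml_s"].median()), 6))  # 0.002017
```

The true drinking rate is 1 row/s × 2.02×10⁻³ mL/row = 2.02×10⁻³ mL/s; with
2 px of measurement noise on the meniscus row, the LOESS-derivative median
recovers it to within 0.2 %. The crop centre (column 382) falls inside the
40 px tube centred at column 400 — edge density is flat across the tube
interior, so any interior column is a correct peak.

The numbered scripts under `analysis/` run the same chain as a narrative:
cohort simulation, ROI accuracy, network training, kinetics recovery and
the behavioral statistics with figures (written under `results/`).

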