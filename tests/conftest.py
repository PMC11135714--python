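"""Shared fixtures: scene samplers and a once-per-session trained meniscus net."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nectartrack.localize import TrainConfig, build_and_train
from nectartrack.scene import LinearLevel, LinearTip, SceneConfig, make_labeled_set
from nectartrack.unet import UNetSpec

HALF_SCALE = 0.5
HALF_CROP = 50  # 100-column ROI at half resolution


def feeding_scene(rng: np.random.Generator, scale: float = HALF_SCALE) -> SceneConfig:
    """A random feeding scene: log-uniform drinking rate, proboscis present."""
    base = SceneConfig(duration=20.0, seed=int(rng.integers(2**31 - 1)))
    cal = base.calibration()
    rate_ml = float(np.exp(rng.uniform(np.log(5e-4), np.log(5e-3))))
    level = LinearLevel(float(rng.uniform(120, 400)), rate_ml / cal.ml_per_pixel)
    tip = LinearTip(level, float(rng.uniform(20, 150)), 400 + float(rng.uniform(-8, 8)))
    sc = dataclasses.replace(base, nectar_level_fn=level, proboscis_fn=tip)
    return sc.scaled(scale) if scale != 1.0 else sc


@pytest.fixture(scope="session")
def labeled_halfres():
    """80 labeled half-resolution cropped frames (64 train / 16 held out)."""
    frames, men, pro = make_labeled_set(80, feeding_scene, seed=1, crop_width=HALF_CROP)
    return frames, men, pro


@pytest.fixture(scope="session")
def trained_meniscus(labeled_halfres):
    """Meniscus U-net trained briefly on the synthetic labeled set."""
    frames, men, _ = labeled_halfres
    spec = UNetSpec(depth=2, filters=(8, 16))
    model, history = build_and_train(
        frames[:64], men[:64], spec, TrainConfig(epochs=18, seed=0)
    )
    return {
        "model": model,
        "history": history,
        "test_frames": frames[64:],
        "test_masks": men[64:],
    }
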