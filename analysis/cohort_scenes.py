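"""Shared scene sampler for the analysis drivers."""

import dataclasses

import numpy as np

from nectartrack.scene import LinearLevel, LinearTip, SceneConfig


def feeding_scene(rng: np.random.Generator, scale: float = 0.5) -> SceneConfig:
    """Random feeding scene: log-uniform drinking rate, proboscis present."""
    base = SceneConfig(duration=20.0, seed=int(rng.integers(2**31 - 1)))
    cal = base.calibration()
    rate_ml = float(np.exp(rng.uniform(np.log(5e-4), np.log(5e-3))))
    level = LinearLevel(float(rng.uniform(120, 400)), rate_ml / cal.ml_per_pixel)
    tip = LinearTip(level, float(rng.uniform(20, 150)), 400 + float(rng.uniform(-8, 8)))
    sc = dataclasses.replace(base, nectar_level_fn=level, proboscis_fn=tip)
    return sc.scaled(scale) if scale != 1.0 else sc
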