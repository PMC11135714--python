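"""End-to-end pipeline: simulate -> crop -> (train) -> track -> rate -> analyze.

Each stage reads the declared outputs of the previous one from disk and
writes its own artifacts plus an entry in the run manifest (parameters,
output checksums, package version), so a run is reproducible and
inspectable.  The tracker stage can either apply trained U-nets or be
bypassed with the simulator's ground-truth table (optionally noised) —
the bypass decouples the kinetics and statistics stages from network
training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .crop import crop_to_roi
from .kinetics import (
    Calibration,
    LoessParams,
    calibrate_from_markers,
    rate_series,
    submergence_series,
)
from .localize import (
    LocalizeParams,
    TrainConfig,
    build_and_train,
    track_from_ground_truth,
    track_recording,
)
from .scene import LinearLevel, LinearTip, Recording, SceneConfig, make_labeled_set, render_recording
from .stats import linear_regression, mann_whitney_u, summaries_frame, summarize_recording
from .unet import UNet, UNetSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "crop", "train", "track", "rate", "analyze")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialisable to/from JSON)."""

    outdir: str = "runs/run0"
    seed: int = 0
    n_recordings: int = 3
    scale: float = 1.0  # 0.5 -> 300x400 frames, proportional geometry
    duration_s: float = 20.0
    fps: float = 10.0
    rate_range_ml_s: tuple[float, float] = (5e-4, 5e-3)
    noise_sigma: float = 2.0
    shadow_strength: float = 0.2
    use_network: bool = False
    train_frames: int = 48
    epochs: int = 12
    unet_depth: int = 2
    unet_filters: tuple[int, ...] = (8, 16)
    mask_threshold: float = 0.5
    contamination: float = 0.05
    track_noise_sigma: float = 0.0  # bypass-mode injected row noise
    loess_frac: float = 0.5
    loess_degree: int = 1
    log_level: str = "INFO"

    @property
    def crop_width(self) -> int:
        return max(16, int(round(100 * self.scale)))

    def loess_params(self) -> LoessParams:
        return LoessParams(frac=self.loess_frac, degree=self.loess_degree)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str | Path) -> "RunConfig":
        if isinstance(text, Path):
            text = text.read_text()
        d = json.loads(text)
        d["rate_range_ml_s"] = tuple(d.get("rate_range_ml_s", (5e-4, 5e-3)))
        d["unet_filters"] = tuple(d.get("unet_filters", (8, 16)))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scene_for(cfg: RunConfig, idx: int, rng: np.random.Generator) -> SceneConfig:
    lo, hi = cfg.rate_range_ml_s
    base = SceneConfig(duration=cfg.duration_s, fps=cfg.fps,
                       noise_sigma=cfg.noise_sigma, shadow_strength=cfg.shadow_strength,
                       seed=int(rng.integers(2**31 - 1)))
    cal = base.calibration()
    rate_ml = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    rows_per_s = rate_ml / cal.ml_per_pixel
    start = float(rng.uniform(120, 200))
    level = LinearLevel(start, rows_per_s)
    depth_rows = float(rng.uniform(20, 200))
    tip = LinearTip(level, depth_rows, base.tube_center_col + float(rng.uniform(-8, 8)))
    sc = dataclasses.replace(base, nectar_level_fn=level, proboscis_fn=tip)
    return sc.scaled(cfg.scale) if cfg.scale != 1.0 else sc


def _rec_dirs(out: Path, cfg: RunConfig) -> list[Path]:
    return [out / "recordings" / f"rec_{i:03d}" for i in range(cfg.n_recordings)]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {path.name} from stage '{stage}'; run '{stage}' first"
        )
    return path


def run_pipeline(cfg: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text())
        if manifest_path.exists()
        else {"version": __version__, "config": json.loads(cfg.to_json()), "stages": {}}
    )
    stages = [s for s in stages if s != "train" or cfg.use_network]
    for stage in stages:
        if stage not in ALL_STAGES:
            raise PipelineError(f"unknown stage '{stage}'")
        logger.info("running stage %s", stage)
        outputs = _STAGE_FUNCS[stage](cfg, out)
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs if p.is_file()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    rng = np.random.default_rng(cfg.seed)
    written = []
    for i, rdir in enumerate(_rec_dirs(out, cfg)):
        sc = _scene_for(cfg, i, rng)
        rec, gt = render_recording(sc)
        rec.save_frames(rdir / "frames")
        gt_path = rdir / "gt.csv"
        rdir.mkdir(parents=True, exist_ok=True)
        gt.to_csv(gt_path, index=False)
        behavior = "perched" if i % 3 == 2 else "hovering"
        meta = {
            "recording_id": f"rec_{i:03d}",
            "moth_id": f"M{i % 4:02d}",
            "behavior": behavior,
            "proboscis": "extended",
            "fps": sc.fps,
            "marking_rows": list(sc.marking_rows),
            "marked_volumes": list(sc.marked_volumes),
            "syringe_mm_per_ml": sc.syringe_mm_per_ml,
            "tube_center_col": sc.tube_center_col,
        }
        meta_path = rdir / "meta.json"
        meta_path.write_text(json.dumps(meta, indent=2))
        written += [gt_path, meta_path]
    return written


def _stage_crop(cfg: RunConfig, out: Path) -> list[Path]:
    written = []
    for rdir in _rec_dirs(out, cfg):
        frames_dir = _require(rdir / "frames", "simulate", "crop")
        meta = json.loads((rdir / "meta.json").read_text())
        rec = Recording.load_frames(frames_dir, fps=meta["fps"])
        # flower is stationary on the stage: one window per recording
        _, window = crop_to_roi(rec.frames[0], width=cfg.crop_width)
        cropped = rec.frames[:, :, window.col_lo : window.col_hi]
        np.save(rdir / "cropped.npy", cropped)
        wpath = rdir / "window.json"
        wpath.write_text(window.to_json())
        written.append(wpath)
    return written


def _labeled_sampler(cfg: RunConfig):
    def sampler(rng: np.random.Generator) -> SceneConfig:
        inner = np.random.default_rng(rng.integers(2**31 - 1))
        return _scene_for(cfg, 0, inner)

    return sampler


def _stage_train(cfg: RunConfig, out: Path) -> list[Path]:
    frames, men_masks, pro_masks = make_labeled_set(
        cfg.train_frames, _labeled_sampler(cfg), seed=cfg.seed + 1,
        crop_width=cfg.crop_width,
    )
    spec = UNetSpec(depth=cfg.unet_depth, filters=cfg.unet_filters)
    tc = TrainConfig(epochs=cfg.epochs, seed=cfg.seed)
    written = []
    mdir = out / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    for name, masks in (("meniscus", men_masks), ("proboscis", pro_masks)):
        model, history = build_and_train(frames, masks, spec, tc)
        model.save(mdir / f"{name}.npz")
        logger.info("%s net: final loss %.4f", name, history[-1])
        written += [mdir / f"{name}.npz", mdir / f"{name}.json"]
    return written


def _stage_track(cfg: RunConfig, out: Path) -> list[Path]:
    written = []
    params = LocalizeParams(mask_threshold=cfg.mask_threshold)
    men_model = pro_model = None
    if cfg.use_network:
        mpath = _require(out / "models" / "meniscus.npz", "train", "track")
        men_model = UNet.load(mpath)
        pro_model = UNet.load(out / "models" / "proboscis.npz")
    for i, rdir in enumerate(_rec_dirs(out, cfg)):
        meta = json.loads(_require(rdir / "meta.json", "simulate", "track").read_text())
        if cfg.use_network:
            cropped = np.load(_require(rdir / "cropped.npy", "crop", "track"))
            track = track_recording(
                men_model, pro_model, cropped, fps=meta["fps"], params=params,
                contamination=cfg.contamination, seed=cfg.seed,
            )
        else:
            gt = pd.read_csv(_require(rdir / "gt.csv", "simulate", "track"))
            track = track_from_ground_truth(
                gt, row_noise_sigma=cfg.track_noise_sigma,
                tip_noise_sigma=cfg.track_noise_sigma, seed=cfg.seed + i,
            )
        tpath = rdir / "track.csv"
        track.to_csv(tpath, index=False)
        written.append(tpath)
    return written


def _stage_rate(cfg: RunConfig, out: Path) -> list[Path]:
    written = []
    for rdir in _rec_dirs(out, cfg):
        meta = json.loads(_require(rdir / "meta.json", "simulate", "rate").read_text())
        track = pd.read_csv(_require(rdir / "track.csv", "track", "rate"))
        cal = calibrate_from_markers(
            meta["marking_rows"], meta["marked_volumes"],
            syringe_mm_per_ml=meta["syringe_mm_per_ml"],
        )
        (rdir / "calibration.json").write_text(cal.to_json())
        rate = rate_series(track, cal, cfg.loess_params())
        sub = submergence_series(track, cal)
        rate.to_csv(rdir / "rate.csv", index=False)
        sub.to_csv(rdir / "submergence.csv", index=False)
        written += [rdir / "rate.csv", rdir / "submergence.csv", rdir / "calibration.json"]
    return written


def _stage_analyze(cfg: RunConfig, out: Path) -> list[Path]:
    summaries = []
    for rdir in _rec_dirs(out, cfg):
        meta = json.loads(_require(rdir / "meta.json", "simulate", "analyze").read_text())
        rate = pd.read_csv(_require(rdir / "rate.csv", "rate", "analyze"))
        sub = pd.read_csv(rdir / "submergence.csv")
        summaries.append(summarize_recording(rate, sub, meta))
    df = summaries_frame(summaries)
    spath = out / "summary.csv"
    df.to_csv(spath, index=False)

    results: dict = {"n_recordings": len(df), "n_usable": int(df["usable"].sum())}
    usable = df.loc[df["usable"] & df["median_sub_mm"].notna()]
    if len(usable) >= 3 and np.ptp(usable["median_sub_mm"].to_numpy()) > 0:
        reg = linear_regression(usable["median_sub_mm"], usable["median_rate_ml_s"])
        results["submergence_vs_rate"] = {
            "slope": reg.slope, "r": reg.r, "p": reg.p_value, "n": reg.n,
        }
    hov = df.loc[df["behavior"] == "hovering", "median_rate_ml_s"].dropna()
    per = df.loc[df["behavior"] == "perched", "median_rate_ml_s"].dropna()
    if len(hov) > 0 and len(per) > 0:
        mw = mann_whitney_u(hov, per)
        results["hovering_vs_perched"] = {
            "U": mw.statistic, "p": mw.p_value, "n": list(mw.n),
        }
    jpath = out / "stats.json"
    jpath.write_text(json.dumps(results, indent=2))
    return [spath, jpath]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "crop": _stage_crop,
    "train": _stage_train,
    "track": _stage_track,
    "rate": _stage_rate,
    "analyze": _stage_analyze,
}
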