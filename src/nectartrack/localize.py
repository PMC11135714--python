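"""Object localization: training, mask post-processing and outlier rejection.

Two U-nets of the same architecture are trained, one for the nectar
meniscus and one for the proboscis tip.  Network outputs are per-pixel
probabilities; thresholding at 0.5 gives binary masks whose connected
components are measured with ``skimage.measure``.  The largest object is
taken as the meniscus; for the proboscis — which shadows near the tube
walls can split into several fragments — the object whose bounding-box
bottom edge lies furthest from the top of the image is selected and its
bottom-most pixel reported as the tip.  Implausible meniscus measurements
are flagged by an isolation forest fitted on simple spatial/temporal
features and excluded from rate fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops
from sklearn.ensemble import IsolationForest

from .unet import AdamW, UNet, UNetSpec, bce_with_logits

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LocalizeParams",
    "MeniscusMeasure",
    "build_and_train",
    "predict_mask",
    "select_meniscus",
    "select_proboscis_tip",
    "filter_outliers",
    "iou",
    "track_recording",
    "track_from_ground_truth",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = [
    "frame", "time_s", "meniscus_row", "meniscus_col", "area",
    "tip_row", "tip_col", "outlier",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; weight decay defaults to 0.0005."""

    epochs: int = 30
    batch_size: int = 8
    lr: float = 2e-3
    weight_decay: float = 0.0005
    seed: int = 0
    augment: bool = True
    max_shift_px: int = 4
    aug_noise_sigma: float = 3.0
    pos_weight: Optional[float] = None  # None -> balance from label frequency


@dataclass(frozen=True)
class LocalizeParams:
    """Mask conversion settings: probability threshold (default 0.5)."""

    mask_threshold: float = 0.5
    target: str = "meniscus"

    def __post_init__(self) -> None:
        if not (0 < self.mask_threshold < 1):
            raise ValueError("mask_threshold must be in (0, 1)")
        if self.target not in ("meniscus", "proboscis"):
            raise ValueError("target must be 'meniscus' or 'proboscis'")


class MeniscusMeasure(NamedTuple):
    row: float
    col: float
    area: int
    bbox: tuple[int, int, int, int]


def _augment_batch(x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Label-geometry-preserving augmentation: horizontal flips, small
    translations (applied to frame and mask alike), brightness/contrast
    jitter and Gaussian noise (image only)."""
    x = x.copy()
    y = y.copy()
    n = x.shape[0]
    for i in range(n):
        if rng.random() < 0.5:
            x[i] = x[i, :, ::-1]
            y[i] = y[i, :, ::-1]
        dr = int(rng.integers(-cfg.max_shift_px, cfg.max_shift_px + 1))
        dc = int(rng.integers(-cfg.max_shift_px, cfg.max_shift_px + 1))
        if dr or dc:
            x[i] = np.roll(x[i], (dr, dc), axis=(0, 1))
            y[i] = np.roll(y[i], (dr, dc), axis=(0, 1))
        gain = 1.0 + rng.normal(0, 0.08)
        bias = rng.normal(0, 0.04)
        x[i] = gain * x[i] + bias
    x += rng.normal(0, cfg.aug_noise_sigma / 255.0, size=x.shape).astype(np.float32)
    return x, y


def build_and_train(
    frames: np.ndarray,
    masks: np.ndarray,
    spec: UNetSpec = UNetSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[UNet, list[float]]:
    """Train a U-net on a labeled set of frames and binary masks.

    Returns the model and the per-epoch mean loss history.  Training is
    seeded: identical data and config reproduce the same model.
    """
    frames = np.asarray(frames)
    masks = np.asarray(masks)
    if frames.shape != masks.shape or frames.ndim != 3:
        raise ValueError(
            f"frames {frames.shape} and masks {masks.shape} must both be (n, h, w)"
        )
    if frames.shape[0] == 0:
        raise ValueError("labeled set is empty")
    x = frames.astype(np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    y = (masks > 0).astype(np.float32)

    if cfg.pos_weight is None:
        pos = y.mean()
        pos_weight = float(np.clip((1 - pos) / max(pos, 1e-6), 1.0, 40.0))
    else:
        pos_weight = cfg.pos_weight

    model = UNet(spec, seed=cfg.seed)
    opt = AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    history: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            if cfg.augment:
                xb, yb = _augment_batch(xb, yb, cfg, rng)
            logits = model.forward(xb)
            loss, dlogits = bce_with_logits(logits, yb, pos_weight=pos_weight)
            grads = model.backward(dlogits)
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_mask(model: UNet, frame: np.ndarray, params: LocalizeParams) -> np.ndarray:
    """Probability map thresholded at ``params.mask_threshold`` (default 0.5)."""
    proba = model.predict_proba(frame)
    return proba >= params.mask_threshold


def select_meniscus(mask: np.ndarray) -> Optional[MeniscusMeasure]:
    """Centroid and geometry of the largest connected component.

    The meniscus spans the tube interior, so it is the biggest object in a
    correct mask; smaller spurious blobs are ignored.  Empty mask -> None.
    """
    lab = label(np.asarray(mask).astype(bool))
    regions = regionprops(lab)
    if not regions:
        return None
    best = max(regions, key=lambda r: (r.area, -r.label))
    return MeniscusMeasure(
        row=float(best.centroid[0]),
        col=float(best.centroid[1]),
        area=int(best.area),
        bbox=tuple(best.bbox),
    )


def select_proboscis_tip(mask: np.ndarray) -> Optional[tuple[float, float]]:
    """Tip of the component whose bounding box reaches lowest in the image.

    Shadows can fragment the proboscis; the deepest fragment contains the
    tip.  The tip is the component's bottom-most pixel (column midpoint if
    several pixels tie).  Empty mask -> None.
    """
    m = np.asarray(mask).astype(bool)
    lab = label(m)
    regions = regionprops(lab)
    if not regions:
        return None
    best = max(regions, key=lambda r: (r.bbox[2], -r.label))
    rows, cols = np.nonzero(lab == best.label)
    bottom = rows.max()
    tie_cols = cols[rows == bottom]
    return (float(bottom), float((tie_cols.min() + tie_cols.max()) / 2.0))


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two same-shape binary masks.

    Defined as 0 when both masks are empty (such frames are excluded from
    performance summaries).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def filter_outliers(
    track: pd.DataFrame, contamination: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Flag implausible meniscus measurements with an isolation forest.

    Features per frame: centroid row and column, region area, and the
    frame-to-frame row displacement — so both spatially odd detections and
    sudden jumps are isolated.  Flags are only ever set on meniscus
    measurements; with fewer than 10 of them no filtering is attempted.
    """
    out = track.copy()
    out["outlier"] = False
    ok = out["meniscus_row"].notna()
    if ok.sum() < 10:
        warnings.warn("fewer than 10 meniscus measurements; skipping outlier filter")
        return out
    sub = out.loc[ok]
    rows = sub["meniscus_row"].to_numpy(dtype=float)
    disp = np.diff(rows, prepend=rows[0])
    cols = sub.get("meniscus_col", pd.Series(np.zeros(len(sub)))).to_numpy(dtype=float)
    area = sub.get("area", pd.Series(np.zeros(len(sub)))).to_numpy(dtype=float)
    feats = np.column_stack([rows, cols, area, disp])
    forest = IsolationForest(
        n_estimators=100, contamination=contamination, random_state=seed
    )
    flags = forest.fit_predict(feats) == -1
    out.loc[sub.index, "outlier"] = flags
    return out


# ---------------------------------------------------------------------------
# track construction
# ---------------------------------------------------------------------------

def track_recording(
    meniscus_model: UNet,
    proboscis_model: Optional[UNet],
    frames: np.ndarray,
    fps: float,
    params: LocalizeParams = LocalizeParams(),
    contamination: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run both localizers over cropped frames and assemble a TrackTable."""
    rows = []
    men_proba = meniscus_model.predict_proba(frames)
    pro_proba = proboscis_model.predict_proba(frames) if proboscis_model else None
    for i in range(frames.shape[0]):
        rec: dict = {"frame": i, "time_s": i / fps, "meniscus_row": np.nan,
                     "meniscus_col": np.nan, "area": np.nan,
                     "tip_row": np.nan, "tip_col": np.nan, "outlier": False}
        m = select_meniscus(men_proba[i] >= params.mask_threshold)
        if m is not None:
            rec.update(meniscus_row=m.row, meniscus_col=m.col, area=m.area)
        if pro_proba is not None:
            tip = select_proboscis_tip(pro_proba[i] >= params.mask_threshold)
            if tip is not None:
                rec.update(tip_row=tip[0], tip_col=tip[1])
        rows.append(rec)
    track = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return filter_outliers(track, contamination=contamination, seed=seed)


def track_from_ground_truth(
    gt: pd.DataFrame,
    row_noise_sigma: float = 0.0,
    tip_noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """TrackTable built from a ground-truth table, with optional injected noise.

    This bypass stands in for the network tracker so the kinetics and
    statistics stages can be exercised against exact answers.
    """
    rng = np.random.default_rng(seed)
    n = len(gt)
    track = pd.DataFrame(
        {
            "frame": gt["frame"].to_numpy(),
            "time_s": gt["time_s"].to_numpy(),
            "meniscus_row": gt["meniscus_row"].to_numpy()
            + (rng.normal(0, row_noise_sigma, n) if row_noise_sigma > 0 else 0.0),
            "meniscus_col": np.zeros(n),
            "area": np.zeros(n),
            "tip_row": gt["tip_row"].to_numpy()
            + (rng.normal(0, tip_noise_sigma, n) if tip_noise_sigma > 0 else 0.0),
            "tip_col": gt["tip_col"].to_numpy(),
            "outlier": np.zeros(n, dtype=bool),
        }
    )
    return track
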