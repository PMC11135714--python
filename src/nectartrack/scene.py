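"""Synthetic artificial-flower scenes with exact ground truth.

Renders the kind of image a backlit nectar-feeding assay produces: a bright
diffuse background, a vertical syringe tube with horizontal volume
graduations, a dark nectar column whose meniscus descends as the moth
drinks, and a thin proboscis reaching down into the fluid.  Every rendered
recording carries a ground-truth table (true meniscus row, proboscis tip,
instantaneous ingestion rate) so downstream stages can be verified against
known answers.

Coordinate convention: row 0 is the top of the image and rows increase
downward, so a falling nectar level means an increasing meniscus row.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, line

from .kinetics import calibrate_from_markers

__all__ = [
    "SceneConfigError",
    "LinearLevel",
    "LinearTip",
    "SceneConfig",
    "Recording",
    "render_frame",
    "render_recording",
    "make_labeled_set",
    "num_frames",
    "meniscus_mask_for",
    "proboscis_mask_for",
]


class SceneConfigError(ValueError):
    """Scene configuration places content outside the frame or is inconsistent."""


@dataclass(frozen=True)
class LinearLevel:
    """Meniscus row trajectory with constant descent speed (rows/s).

    Carries its analytic derivative so ground-truth rates are exact.
    """

    start_row: float
    rows_per_s: float = 0.0

    def __call__(self, t: float) -> float:
        return self.start_row + self.rows_per_s * t

    def rate(self, t: float) -> float:
        return self.rows_per_s


@dataclass(frozen=True)
class LinearTip:
    """Proboscis tip held at a fixed offset below the meniscus."""

    level: LinearLevel
    depth_rows: float
    col: float

    def __call__(self, t: float):
        return (self.level(t) + self.depth_rows, self.col)


def _default_markings(height: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    # ten graduations of a 1 mL syringe, 0.1 mL apart, spanning most of the frame
    rows = tuple(int(round(height * 0.1 + i * height * 0.0825)) for i in range(10))
    volumes = tuple(round(1.0 - 0.1 * i, 10) for i in range(10))
    return rows, volumes


@dataclass
class SceneConfig:
    """Geometry, photometry and kinematics of one synthetic recording.

    Grey levels emulate a backlit near-IR scene: bright background, darker
    translucent nectar, nearly opaque tube walls and proboscis.
    """

    frame_height: int = 600
    frame_width: int = 800
    tube_center_col: int = 400
    tube_width: int = 40
    marking_rows: Sequence[int] = ()
    marked_volumes: Sequence[float] = ()
    nectar_level_fn: Callable[[float], float] = field(
        default_factory=lambda: LinearLevel(150.0, 1.0)
    )
    nectar_level_rate_fn: Optional[Callable[[float], float]] = None
    proboscis_fn: Optional[Callable[[float], tuple[float, float]]] = None
    noise_sigma: float = 2.0
    shadow_strength: float = 0.0
    fps: float = 10.0
    duration: float = 20.0
    seed: int = 0
    # photometry (grey levels, 0-255)
    background_grey: float = 230.0
    nectar_grey: float = 150.0
    wall_grey: float = 30.0
    marking_grey: float = 60.0
    meniscus_grey: float = 70.0
    proboscis_grey: float = 45.0
    syringe_mm_per_ml: float = 58.0

    def __post_init__(self) -> None:
        if not self.marking_rows:
            rows, vols = _default_markings(self.frame_height)
            self.marking_rows = rows
            self.marked_volumes = vols
        if not (0 < self.tube_width < self.frame_width):
            raise SceneConfigError(
                f"tube_width {self.tube_width} must lie in (0, {self.frame_width})"
            )
        bad = [r for r in self.marking_rows if not (0 <= r < self.frame_height)]
        if bad:
            raise SceneConfigError(f"marking_rows outside frame: {bad}")
        if len(self.marking_rows) != len(self.marked_volumes):
            raise SceneConfigError("marking_rows and marked_volumes differ in length")
        if self.duration <= 0 or self.fps <= 0:
            raise SceneConfigError("duration and fps must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def wall_px(self) -> int:
        return max(2, self.tube_width // 20)

    @property
    def interior_cols(self) -> tuple[int, int]:
        """[lo, hi) columns of the tube interior (between the walls)."""
        half = self.tube_width // 2
        lo = self.tube_center_col - half + self.wall_px
        hi = self.tube_center_col + half - self.wall_px
        return lo, hi

    def level_rate(self, t: float) -> float:
        """Meniscus descent speed in rows/s (analytic when available)."""
        if self.nectar_level_rate_fn is not None:
            return float(self.nectar_level_rate_fn(t))
        rate = getattr(self.nectar_level_fn, "rate", None)
        if callable(rate):
            return float(rate(t))
        h = 1e-4
        lo = max(0.0, t - h)
        hi = min(self.duration, t + h)
        return (self.nectar_level_fn(hi) - self.nectar_level_fn(lo)) / (hi - lo)

    def calibration(self):
        return calibrate_from_markers(
            np.asarray(self.marking_rows, dtype=float),
            np.asarray(self.marked_volumes, dtype=float),
            syringe_mm_per_ml=self.syringe_mm_per_ml,
        )

    def scaled(self, factor: float) -> "SceneConfig":
        """Proportionally reduced-resolution copy (e.g. factor=0.5 -> 300x400)."""
        base_level = self.nectar_level_fn
        base_rate = self.nectar_level_rate_fn
        level = _ScaledLevel(base_level, factor, base_rate)
        prob = None
        if self.proboscis_fn is not None:
            base_prob = self.proboscis_fn
            prob = lambda t: tuple(factor * v for v in base_prob(t))  # noqa: E731
        return dataclasses.replace(
            self,
            frame_height=int(round(self.frame_height * factor)),
            frame_width=int(round(self.frame_width * factor)),
            tube_center_col=int(round(self.tube_center_col * factor)),
            tube_width=max(6, int(round(self.tube_width * factor))),
            marking_rows=tuple(int(round(r * factor)) for r in self.marking_rows),
            marked_volumes=tuple(self.marked_volumes),
            nectar_level_fn=level,
            nectar_level_rate_fn=None,
            proboscis_fn=prob,
        )

    def to_json(self) -> str:
        d = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if not callable(v) and k not in ("nectar_level_fn", "nectar_level_rate_fn", "proboscis_fn")
        }
        lvl = self.nectar_level_fn
        if isinstance(lvl, LinearLevel):
            d["linear_level"] = {"start_row": lvl.start_row, "rows_per_s": lvl.rows_per_s}
        return json.dumps(d, indent=2, default=float)


@dataclass(frozen=True)
class _ScaledLevel:
    base: Callable[[float], float]
    factor: float
    base_rate: Optional[Callable[[float], float]] = None

    def __call__(self, t: float) -> float:
        return self.factor * self.base(t)

    def rate(self, t: float) -> float:
        if self.base_rate is not None:
            return self.factor * self.base_rate(t)
        r = getattr(self.base, "rate", None)
        if callable(r):
            return self.factor * r(t)
        h = 1e-4
        return self.factor * (self.base(t + h) - self.base(t - h)) / (2 * h)


@dataclass
class Recording:
    """An ordered stack of grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (n, height, width) uint8
    fps: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def save_frames(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, frame in enumerate(self.frames):
            p = directory / f"frame_{i:05d}.png"
            iio.imwrite(p, frame)
            paths.append(p)
        return paths

    @classmethod
    def load_frames(cls, directory: str | Path, fps: float) -> "Recording":
        paths = sorted(Path(directory).glob("frame_*.png"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.png files under {directory}")
        frames = np.stack([iio.imread(p) for p in paths])
        return cls(frames=frames, fps=fps)


def num_frames(duration: float, fps: float) -> int:
    """Frame count of a recording: floor(duration * fps)."""
    return int(np.floor(duration * fps))


def _draw_polyline(img: np.ndarray, pts: list[tuple[float, float]], grey: float, width: int = 2) -> None:
    h, w = img.shape
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        for dc in range(width):
            cc2 = np.clip(cc + dc, 0, w - 1)
            rr2 = np.clip(rr, 0, h - 1)
            img[rr2, cc2] = grey


def render_frame(
    config: SceneConfig, t: float, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Render one frame of the synthetic scene at time ``t`` (seconds).

    With ``rng`` omitted, noise is seeded from ``config.seed`` alone, so the
    same (config, t) always renders the same pixels.
    """
    if not (0.0 <= t <= config.duration):
        raise ValueError(f"t={t} outside recording [0, {config.duration}]")
    h, w = config.frame_height, config.frame_width
    img = np.full((h, w), config.background_grey, dtype=np.float64)

    half = config.tube_width // 2
    wall = config.wall_px
    c = config.tube_center_col
    lo_wall, hi_wall = c - half, c + half
    if lo_wall < 0 or hi_wall > w:
        raise SceneConfigError("tube extends outside frame")
    in_lo, in_hi = config.interior_cols

    m_row = float(config.nectar_level_fn(t))
    if not (1.0 <= m_row <= h - 2):
        raise SceneConfigError(
            f"meniscus row {m_row:.1f} at t={t:.2f}s outside frame of height {h}"
        )

    # tube walls
    img[:, lo_wall : lo_wall + wall] = config.wall_grey
    img[:, hi_wall - wall : hi_wall] = config.wall_grey
    # nectar column below the meniscus (translucent: backlight passes through)
    nectar_top = int(np.ceil(m_row))
    img[nectar_top:, in_lo:in_hi] = config.nectar_grey
    # volume graduations across the interior
    for r in config.marking_rows:
        img[r : min(r + 2, h), in_lo:in_hi] = config.marking_grey
    # meniscus: a dark band where the curved fluid surface scatters the light
    b0 = int(round(m_row)) - 1
    img[max(b0, 0) : min(b0 + 3, h), in_lo:in_hi] = config.meniscus_grey

    # proboscis: jointed polyline from the top of the frame to the tip
    if config.proboscis_fn is not None:
        tip = config.proboscis_fn(t)
        if tip is not None:
            tip_r, tip_c = float(tip[0]), float(tip[1])
            if not (0 <= tip_r < h and 0 <= tip_c < w):
                raise SceneConfigError(f"proboscis tip {tip} outside frame")
            entry_c = tip_c + 0.15 * config.tube_width
            mid = (0.45 * tip_r, tip_c - 0.05 * config.tube_width)
            _draw_polyline(
                img, [(0.0, entry_c), mid, (tip_r, tip_c)], config.proboscis_grey
            )

    # optional shadows hugging the inside of the tube walls
    if config.shadow_strength > 0:
        band = max(1, config.tube_width // 8)
        factor = 1.0 - 0.6 * float(config.shadow_strength)
        img[:, in_lo : in_lo + band] *= factor
        img[:, in_hi - band : in_hi] *= factor

    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_recording(config: SceneConfig) -> tuple[Recording, pd.DataFrame]:
    """Render all frames of a recording and its ground-truth table.

    Returns the recording and a table with one row per frame:
    frame, time_s, meniscus_row, tip_row, tip_col, rate_ml_s.  The true
    rate is the analytic meniscus speed converted through the marker
    calibration (positive while the level falls).
    """
    n = num_frames(config.duration, config.fps)
    if n < 2:
        raise SceneConfigError("recording must span at least 2 frames")
    cal = config.calibration()
    frames = np.empty((n, config.frame_height, config.frame_width), dtype=np.uint8)
    rows = []
    for i in range(n):
        t = i / config.fps
        rng = np.random.default_rng([config.seed, i])
        frames[i] = render_frame(config, t, rng)
        tip = config.proboscis_fn(t) if config.proboscis_fn is not None else None
        rows.append(
            {
                "frame": i,
                "time_s": t,
                "meniscus_row": float(config.nectar_level_fn(t)),
                "tip_row": float(tip[0]) if tip is not None else np.nan,
                "tip_col": float(tip[1]) if tip is not None else np.nan,
                "rate_ml_s": config.level_rate(t) * cal.ml_per_pixel,
            }
        )
    gt = pd.DataFrame(rows)
    rec = Recording(frames=frames, fps=config.fps, metadata={"seed": config.seed})
    return rec, gt


# ---------------------------------------------------------------------------
# labeled datasets for the localization networks
# ---------------------------------------------------------------------------

def meniscus_mask_for(config: SceneConfig, m_row: float) -> np.ndarray:
    """Binary mask: 3-row band at the meniscus across the tube interior."""
    mask = np.zeros((config.frame_height, config.frame_width), dtype=np.uint8)
    in_lo, in_hi = config.interior_cols
    b0 = int(round(m_row)) - 1
    mask[max(b0, 0) : min(b0 + 3, config.frame_height), in_lo:in_hi] = 1
    return mask


def proboscis_mask_for(config: SceneConfig, tip: Optional[tuple[float, float]]) -> np.ndarray:
    """Binary mask: small disk at the proboscis tip (all-zero when absent)."""
    mask = np.zeros((config.frame_height, config.frame_width), dtype=np.uint8)
    if tip is None:
        return mask
    rr, cc = disk((tip[0], tip[1]), radius=3.2, shape=mask.shape)
    mask[rr, cc] = 1
    return mask


def make_labeled_set(
    n_frames: int,
    config_sampler: Callable[[np.random.Generator], SceneConfig],
    seed: int = 0,
    crop_width: Optional[int] = None,
):
    """Sample labeled (frame, meniscus mask, proboscis mask) triples.

    ``config_sampler(rng)`` returns the scene for each sample; the frame
    time is drawn uniformly over the scene's duration.  When ``crop_width``
    is given, frames and masks are cropped to that many columns centred on
    the tube, matching what the localization networks consume.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames, men_masks, pro_masks = [], [], []
    for i in range(n_frames):
        cfg = config_sampler(rng)
        t = float(rng.uniform(0.0, cfg.duration))
        frame = render_frame(cfg, t, np.random.default_rng([seed, i, 7]))
        m_row = float(cfg.nectar_level_fn(t))
        tip = cfg.proboscis_fn(t) if cfg.proboscis_fn is not None else None
        mm = meniscus_mask_for(cfg, m_row)
        pm = proboscis_mask_for(cfg, tip)
        if crop_width is not None:
            lo = int(np.clip(cfg.tube_center_col - crop_width // 2, 0, cfg.frame_width - crop_width))
            sl = slice(lo, lo + crop_width)
            frame, mm, pm = frame[:, sl], mm[:, sl], pm[:, sl]
        frames.append(frame)
        men_masks.append(mm)
        pro_masks.append(pm)
    return np.stack(frames), np.stack(men_masks), np.stack(pro_masks)
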