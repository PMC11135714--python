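"""Drinking-rate and proboscis-submergence kinetics.

Meniscus tracks are smoothed with LOESS (locally weighted least squares) and
the drinking rate is the analytic slope of each local polynomial, converted
to mL/s through a recording-specific calibration derived from the syringe's
volume markers.  Submergence is the meniscus-to-tip distance in mm, with
negative values (tip above the fluid) discarded.

Sign convention: image rows grow downward, so a falling nectar level gives a
positive row slope and a positive drinking rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "LoessParams",
    "LoessError",
    "calibrate_from_markers",
    "n_loess_neighbors",
    "loess_fit_with_slope",
    "rate_series",
    "submergence_series",
]


class LoessError(ValueError):
    pass


# slopes of a numerically flat fit come out at +/-1e-17; do not flag those
NEG_RATE_TOL = 1e-12  # mL/s


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical conversion for one recording.

    ml_per_pixel comes from the least-squares slope of marked volume against
    marker row; mm_per_pixel additionally uses the syringe barrel's physical
    length per millilitre.
    """

    ml_per_pixel: float
    mm_per_pixel: float

    def __post_init__(self) -> None:
        for name in ("ml_per_pixel", "mm_per_pixel"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    def to_json(self) -> str:
        return json.dumps({"ml_per_pixel": self.ml_per_pixel, "mm_per_pixel": self.mm_per_pixel})

    @classmethod
    def from_json(cls, text: str) -> "Calibration":
        d = json.loads(text)
        return cls(d["ml_per_pixel"], d["mm_per_pixel"])


def calibrate_from_markers(
    marker_rows, marker_volumes, syringe_mm_per_ml: float = 58.0
) -> Calibration:
    """Calibration from the pixel rows and volumes of syringe graduations.

    ``syringe_mm_per_ml`` is the physical barrel length per millilitre
    (about 58 mm for a 1 mL syringe) and links the volume slope to a
    millimetre scale.
    """
    rows = np.asarray(marker_rows, dtype=float)
    vols = np.asarray(marker_volumes, dtype=float)
    if rows.size < 2 or vols.size != rows.size:
        raise ValueError("need >= 2 markers with matching volumes")
    if np.ptp(rows) == 0:
        raise ValueError("marker rows are all identical; cannot calibrate")
    slope = np.polyfit(rows, vols, 1)[0]
    ml_per_pixel = abs(float(slope))
    if ml_per_pixel == 0:
        raise ValueError("marker volumes do not vary with row; cannot calibrate")
    return Calibration(
        ml_per_pixel=ml_per_pixel, mm_per_pixel=ml_per_pixel * syringe_mm_per_ml
    )


@dataclass(frozen=True)
class LoessParams:
    """Local-regression settings.

    frac: fraction of the points entering each local fit (neighbour count
    is ceil(frac*n)); degree: local polynomial degree (1 or 2); Gaussian
    distance weights with bandwidth set so the farthest included neighbour
    has weight exp(-1/2) relative to the centre, times bandwidth_scale.
    """

    frac: float = 0.5
    degree: int = 1
    bandwidth_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.frac <= 1):
            raise ValueError("frac must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be positive")


def n_loess_neighbors(n: int, frac: float) -> int:
    """Number of points in each local fit: ceil(frac*n) (e.g. 12 for n=24, frac=0.5)."""
    return int(math.ceil(frac * n))


def loess_fit_with_slope(
    t, y, params: LoessParams = LoessParams()
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS fit and its local slope at every input point.

    At each point a degree-``params.degree`` polynomial is fit by weighted
    least squares to the nearest ceil(frac*n) points in ``t`` (Gaussian
    distance weights).  The fitted value is the polynomial at the point and
    the slope is its analytic first derivative there — exact for the local
    model, rather than a finite difference of fitted values.

    Duplicate times are averaged before fitting; outputs align with the
    original inputs (duplicates share their fitted value and slope).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be equal-length 1-D arrays")
    tu, inverse = np.unique(t, return_inverse=True)
    if tu.size != t.size:
        sums = np.bincount(inverse, weights=y)
        counts = np.bincount(inverse)
        yu = sums / counts
    else:
        order = np.argsort(t, kind="stable")
        tu, yu = t[order], y[order]
        inverse = np.empty_like(order)
        inverse[order] = np.arange(t.size)
    n = tu.size
    p = params.degree
    if n < p + 2:
        raise LoessError(f"need at least degree+2={p + 2} distinct points, got {n}")
    k = max(n_loess_neighbors(n, params.frac), p + 1)

    dist = np.abs(tu[:, None] - tu[None, :])  # (n, n)
    # k nearest neighbours per point; stable partial sort keeps ties deterministic
    nbr = np.argsort(dist, axis=1, kind="stable")[:, :k]  # (n, k)
    d = np.take_along_axis(dist, nbr, axis=1)  # (n, k)
    dmax = d.max(axis=1)
    if np.any(dmax == 0) and k > 1:
        bad = tu[np.nonzero(dmax == 0)[0][0]]
        raise LoessError(f"all neighbour times identical around t={bad}")
    h = dmax * params.bandwidth_scale
    w = np.exp(-0.5 * (d / h[:, None]) ** 2)  # (n, k)

    dt = tu[nbr] - tu[:, None]  # centred times, (n, k)
    X = np.stack([dt**j for j in range(p + 1)], axis=2)  # (n, k, p+1)
    yn = yu[nbr]  # (n, k)
    WX = X * w[:, :, None]
    A = np.einsum("nkp,nkq->npq", WX, X)  # (n, p+1, p+1)
    b = np.einsum("nkp,nk->np", WX, yn)  # (n, p+1)
    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise LoessError(f"singular local design: {exc}") from exc
    fitted_u = beta[:, 0]
    slope_u = beta[:, 1]
    return fitted_u[inverse], slope_u[inverse]


def _valid_meniscus(track: pd.DataFrame) -> pd.DataFrame:
    ok = track["meniscus_row"].notna()
    if "outlier" in track.columns:
        ok &= ~track["outlier"].fillna(False).astype(bool)
    return track.loc[ok]


def rate_series(
    track: pd.DataFrame, cal: Calibration, params: LoessParams = LoessParams()
) -> pd.DataFrame:
    """Calibrated drinking-rate series from an outlier-filtered track.

    Columns: frame, time_s, fitted_row, slope_px_s, rate_ml_s, valid.
    Negative rates are implausible (fluid leaving the proboscis) and are
    flagged invalid; they stay in the table but are excluded from summaries.
    """
    if cal is None:
        raise ValueError("rate_series requires a Calibration")
    sub = _valid_meniscus(track)
    if len(sub) < 4:
        raise ValueError(f"need >= 4 valid meniscus points, got {len(sub)}")
    fitted, slope = loess_fit_with_slope(
        sub["time_s"].to_numpy(), sub["meniscus_row"].to_numpy(), params
    )
    rate = slope * cal.ml_per_pixel
    return pd.DataFrame(
        {
            "frame": sub["frame"].to_numpy(),
            "time_s": sub["time_s"].to_numpy(),
            "fitted_row": fitted,
            "slope_px_s": slope,
            "rate_ml_s": rate,
            "valid": rate >= -NEG_RATE_TOL,
        }
    )


def submergence_series(track: pd.DataFrame, cal: Calibration) -> pd.DataFrame:
    """Proboscis submergence depth (mm) per frame.

    submergence = (tip_row - meniscus_row) * mm_per_pixel; frames missing
    either landmark are skipped and negative depths (tip above the fluid)
    are marked not retained.
    """
    ok = track["meniscus_row"].notna() & track["tip_row"].notna()
    if "outlier" in track.columns:
        ok &= ~track["outlier"].fillna(False).astype(bool)
    sub = track.loc[ok]
    depth = (sub["tip_row"].to_numpy() - sub["meniscus_row"].to_numpy()) * cal.mm_per_pixel
    return pd.DataFrame(
        {
            "frame": sub["frame"].to_numpy(),
            "time_s": sub["time_s"].to_numpy(),
            "submergence_mm": depth,
            "retained": depth >= 0,
        }
    )
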