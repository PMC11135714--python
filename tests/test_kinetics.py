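"""LOESS fitting, calibration and rate/submergence series."""

import numpy as np
import pandas as pd
import pytest

from nectartrack.kinetics import (
    Calibration,
    LoessError,
    LoessParams,
    calibrate_from_markers,
    loess_fit_with_slope,
    n_loess_neighbors,
    rate_series,
    submergence_series,
)
from nectartrack.localize import track_from_ground_truth
from nectartrack.scene import LinearLevel, SceneConfig, render_recording


def loess_oracle(t, y, frac, degree, bandwidth_scale=1.0):
    """Independent per-point weighted-least-squares LOESS (naive loops)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    k = max(int(np.ceil(frac * n)), degree + 1)
    fitted = np.empty(n)
    slope = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        nbr = np.argsort(d, kind="stable")[:k]
        dmax = d[nbr].max()
        w = np.exp(-0.5 * (d[nbr] / (dmax * bandwidth_scale)) ** 2)
        X = np.vander(t[nbr] - t[i], degree + 1, increasing=True)
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[nbr], rcond=None)
        fitted[i] = beta[0]
        slope[i] = beta[1]
    return fitted, slope


class TestLoess:
    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("degree", [1, 2])
    def test_affine_data_reproduced_exactly(self, frac, degree):
        t = np.linspace(0.0, 12.0, 30)
        y = 3.0 + 2.0 * t
        fitted, slope = loess_fit_with_slope(t, y, LoessParams(frac=frac, degree=degree))
        np.testing.assert_allclose(fitted, y, atol=1e-9)
        np.testing.assert_allclose(slope, 2.0, atol=1e-9)

    @pytest.mark.parametrize("degree", [1, 2])
    def test_matches_independent_wls_oracle(self, degree):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 10, 20))
        y = 0.5 * t**2 - t + rng.normal(0, 1.0, 20)
        params = LoessParams(frac=0.5, degree=degree)
        fitted, slope = loess_fit_with_slope(t, y, params)
        of, os_ = loess_oracle(t, y, 0.5, degree)
        np.testing.assert_allclose(fitted, of, rtol=1e-9)
        np.testing.assert_allclose(slope, os_, rtol=1e-9)

    def test_neighbor_count_rule(self):
        assert n_loess_neighbors(24, 0.5) == 12
        assert n_loess_neighbors(25, 0.5) == 13
        assert n_loess_neighbors(10, 1.0) == 10

    def test_n24_frac_half_uses_twelve_points(self):
        # oracle restricted to exactly 12 neighbours must agree
        rng = np.random.default_rng(5)
        t = np.arange(24, dtype=float)
        y = 50.0 + 1.3 * t + rng.normal(0, 2, 24)
        fitted, slope = loess_fit_with_slope(t, y, LoessParams(frac=0.5, degree=1))
        of, os_ = loess_oracle(t, y, 0.5, 1)
        np.testing.assert_allclose(fitted, of, rtol=1e-10)
        np.testing.assert_allclose(slope, os_, rtol=1e-10)

    def test_duplicate_times_averaged(self):
        t = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 3.0, 2.0, 3.0, 4.0])
        fitted, slope = loess_fit_with_slope(t, y, LoessParams(frac=1.0))
        assert fitted[1] == fitted[2]
        assert np.isfinite(slope).all()

    def test_degenerate_times_raise(self):
        with pytest.raises(LoessError):
            loess_fit_with_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], LoessParams())

    def test_slope_equivariant_under_y_scaling(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 5, 25))
        y = rng.normal(0, 1, 25)
        _, s1 = loess_fit_with_slope(t, y, LoessParams())
        _, s3 = loess_fit_with_slope(t, 3.0 * y, LoessParams())
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-12)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LoessParams(frac=0.0)
        with pytest.raises(ValueError):
            LoessParams(degree=3)


class TestCalibration:
    def test_two_marker_arithmetic(self):
        cal = calibrate_from_markers([100, 400], [1.0, 0.4])
        assert cal.ml_per_pixel == pytest.approx(0.6 / 300)

    def test_collinear_markers_match_pairwise_slope(self):
        cal3 = calibrate_from_markers([100, 250, 400], [1.0, 0.7, 0.4])
        cal2 = calibrate_from_markers([100, 400], [1.0, 0.4])
        assert cal3.ml_per_pixel == pytest.approx(cal2.ml_per_pixel)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError):
            calibrate_from_markers([100, 100], [1.0, 0.4])

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            calibrate_from_markers([100], [1.0])

    def test_mm_scale_follows_syringe_geometry(self):
        cal = calibrate_from_markers([100, 400], [1.0, 0.4], syringe_mm_per_ml=58.0)
        assert cal.mm_per_pixel == pytest.approx(cal.ml_per_pixel * 58.0)

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            Calibration(ml_per_pixel=0.0, mm_per_pixel=0.1)


def _track(rows, fps=10.0, tip=None):
    n = len(rows)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / fps,
            "meniscus_row": np.asarray(rows, float),
            "meniscus_col": np.zeros(n),
            "area": np.zeros(n),
            "tip_row": np.asarray(tip, float) if tip is not None else np.full(n, np.nan),
            "tip_col": np.zeros(n),
            "outlier": np.zeros(n, dtype=bool),
        }
    )


class TestRateSeries:
    def test_constant_descent_hand_arithmetic(self):
        # 1 row/frame at 10 fps with 2e-4 mL/px -> 2e-3 mL/s everywhere
        cal = Calibration(ml_per_pixel=2e-4, mm_per_pixel=0.1)
        rs = rate_series(_track(100.0 + np.arange(30.0)), cal)
        np.testing.assert_allclose(rs["rate_ml_s"], 2e-3, rtol=1e-9)
        assert rs["valid"].all()

    def test_static_meniscus_rate_zero(self):
        cal = Calibration(ml_per_pixel=2e-4, mm_per_pixel=0.1)
        rs = rate_series(_track(np.full(20, 150.0)), cal)
        np.testing.assert_allclose(rs["rate_ml_s"], 0.0, atol=1e-12)
        assert rs["valid"].all()  # zero is non-negative, not flagged

    def test_noisy_recording_recovers_rate_within_ten_percent(self):
        cfg = SceneConfig(nectar_level_fn=LinearLevel(100.0, 1.5), duration=20.0)
        _, gt = render_recording(cfg.scaled(0.25))
        cal = cfg.scaled(0.25).calibration()
        track = track_from_ground_truth(gt, row_noise_sigma=2.0, seed=4)
        rs = rate_series(track, cal)
        est = rs.loc[rs["valid"], "rate_ml_s"].median()
        true = gt["rate_ml_s"].iloc[0]
        assert abs(est - true) / true < 0.10

    def test_requires_calibration_and_enough_points(self):
        with pytest.raises(ValueError):
            rate_series(_track([1.0, 2.0, 3.0, 4.0]), None)
        with pytest.raises(ValueError):
            rate_series(_track([1.0, 2.0, 3.0]), Calibration(1e-3, 0.1))

    def test_outliers_excluded_from_fit(self):
        cal = Calibration(ml_per_pixel=2e-4, mm_per_pixel=0.1)
        track = _track(100.0 + np.arange(30.0))
        track.loc[10, "meniscus_row"] = 900.0
        track.loc[10, "outlier"] = True
        rs = rate_series(track, cal)
        assert len(rs) == 29
        np.testing.assert_allclose(rs["rate_ml_s"], 2e-3, rtol=1e-9)

    def test_volume_conservation_over_recording(self):
        # gently curved trajectory: integral of rate ~ calibrated displacement
        cal = Calibration(ml_per_pixel=2e-4, mm_per_pixel=0.1)
        t = np.arange(100) / 10.0
        rows = 100.0 + 1.2 * t + 0.02 * t**2
        rs = rate_series(_track(rows), cal)
        integral = (rs["rate_ml_s"] * 0.1).sum()
        displaced = (rows[-1] - rows[0]) * cal.ml_per_pixel
        assert integral == pytest.approx(displaced, rel=0.05)


class TestSubmergence:
    def test_hand_arithmetic(self):
        cal = Calibration(ml_per_pixel=1e-3, mm_per_pixel=0.1)
        track = _track([400.0, 400.0, 400.0, 400.0], tip=[420.0, 390.0, 400.0, np.nan])
        sub = submergence_series(track, cal)
        assert len(sub) == 3  # frame with missing tip skipped
        assert sub["submergence_mm"].iloc[0] == pytest.approx(2.0)
        assert bool(sub["retained"].iloc[0])
        assert sub["submergence_mm"].iloc[1] == pytest.approx(-1.0)
        assert not bool(sub["retained"].iloc[1])
        assert sub["submergence_mm"].iloc[2] == 0.0
        assert bool(sub["retained"].iloc[2])  # boundary inclusive
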