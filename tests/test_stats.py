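"""Recording summaries, rank tests, regressions and the evaporation bound."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nectartrack.stats import (
    StatResult,
    evaporation_bound,
    linear_regression,
    mann_whitney_u,
    null_effect_experiment,
    simulate_daily_intake,
    summarize_recording,
    volume_vs_mass,
)


def _rate_df(rates, fps=10.0, valid=None):
    n = len(rates)
    rates = np.asarray(rates, float)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / fps,
            "fitted_row": np.zeros(n),
            "slope_px_s": np.zeros(n),
            "rate_ml_s": rates,
            "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        }
    )


class TestSummaries:
    def test_median_of_rates(self):
        s = summarize_recording(_rate_df([1e-3, 2e-3, 3e-3, 4e-3, 5e-3]), None, {})
        assert s.median_rate_ml_s == pytest.approx(3e-3)
        assert s.usable

    def test_total_volume_of_constant_rate(self):
        rate = 2e-3
        s = summarize_recording(_rate_df(np.full(200, rate)), None, {})
        assert s.total_ml == pytest.approx(rate * 20.0, rel=0.02)

    def test_all_invalid_marks_unusable(self):
        s = summarize_recording(_rate_df([1e-3] * 5, valid=[False] * 5), None, {})
        assert not s.usable

    def test_submergence_median_over_retained_only(self):
        sub = pd.DataFrame(
            {
                "frame": range(4),
                "time_s": np.arange(4) / 10,
                "submergence_mm": [5.0, 7.0, -2.0, 9.0],
                "retained": [True, True, False, True],
            }
        )
        s = summarize_recording(_rate_df([1e-3] * 5), sub, {})
        assert s.median_sub_mm == pytest.approx(7.0)


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of rank subsets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    center = na * nb / 2.0
    count = 0
    total = 0
    all_ranks = np.arange(1, na + nb + 1)
    for comb in itertools.combinations(range(na + nb), na):
        u = all_ranks[list(comb)].sum() - na * (na + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * (1/20)
        assert res.method.endswith("exact")

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 7, size=2)
        vals = rng.permutation(np.arange(1.0, na + nb + 1))
        a, b = vals[:na], vals[na:]
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30).round(1)  # rounding induces ties
        b = rng.normal(0.5, 1, 25).round(1)
        res = mann_whitney_u(a, b)
        assert res.method.endswith("asymptotic")
        assert 0.0 <= res.p_value <= 1.0


class TestLinearRegression:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 10)
        y = 1.5 * x - 2.0 + rng.normal(0, 1, 10)
        reg = linear_regression(x, y)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0])
        assert reg.slope == pytest.approx(beta[1])

    def test_p_value_affine_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 15)
        y = 0.3 * x + rng.normal(0, 0.2, 15)
        p1 = linear_regression(x, y).p_value
        p2 = linear_regression(5 + 100 * x, -3 + 0.01 * y).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_collinear_data(self):
        x = np.arange(10.0)
        reg = linear_regression(x, 2 * x + 1)
        assert reg.r == pytest.approx(1.0)
        assert reg.p_value <= 1e-12

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression(np.ones(5), np.arange(5.0))

    def test_confidence_band_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 12)
        y = 2.0 + 0.7 * x + rng.normal(0, 1, 12)
        reg = linear_regression(x, y)
        xq = np.linspace(0, 10, 5)
        lo, hi = reg.band(xq, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        pred = ols.get_prediction(sm.add_constant(xq)).conf_int(alpha=0.05)
        np.testing.assert_allclose(lo, pred[:, 0], rtol=1e-8)
        np.testing.assert_allclose(hi, pred[:, 1], rtol=1e-8)


class TestEvaporation:
    def test_paper_scale_bound(self):
        # 200 uL/day over 600 s -> ~1.4e-3 mL
        assert evaporation_bound(200.0, 600.0) == pytest.approx(1.3889e-3, rel=1e-3)

    def test_zero_duration(self):
        assert evaporation_bound(500.0, 0.0) == 0.0

    def test_linearity_in_rate(self):
        assert evaporation_bound(100.0, 600.0) == pytest.approx(
            evaporation_bound(200.0, 600.0) / 2
        )


class TestVolumeVsMass:
    def test_exact_equality_gives_unit_slope(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        reg, all_le = volume_vs_mass(v, v)
        assert reg.slope == pytest.approx(1.0)
        assert reg.r == pytest.approx(1.0)
        assert all_le

    def test_partial_capture_simulation(self):
        df = simulate_daily_intake(n_days=24, seed=6)
        reg, all_le = volume_vs_mass(df["volume_ml"], df["mass_change_ml"])
        assert reg.slope < 1.0
        assert reg.r > 0.0
        assert reg.p_value < 0.05
        assert all_le  # video never over-counts the balance

    def test_zero_intake_days_handled(self):
        m = np.array([0.0, 0.1, 0.2, 0.3])
        v = np.array([0.0, 0.05, 0.1, 0.2])
        reg, _ = volume_vs_mass(v, m)
        assert np.isfinite(reg.p_value)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            volume_vs_mass([0.1, 0.2], [0.1, 0.2])


class TestNullEffectExperiment:
    def test_returns_regressions_and_summaries(self):
        res = null_effect_experiment(10, 0.0, seed=0)
        assert 0.0 <= res["full"].p_value <= 1.0
        assert len(res["summaries"]) == 10

    def test_insufficient_recordings_rejected(self):
        with pytest.raises(ValueError):
            null_effect_experiment(1, 0.0, seed=0)

    def test_strong_effect_detected(self):
        res = null_effect_experiment(
            30, 1e-4, seed=1, base_rate_range=(9e-4, 1.1e-3)
        )
        assert res["full"].p_value < 0.05
        assert res["full"].slope > 0


def test_stat_result_validates_p():
    with pytest.raises(ValueError):
        StatResult(1.0, 1.5, (3,), "x")
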