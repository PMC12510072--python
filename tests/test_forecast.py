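"""Model fitting, closed-form forecast oracles, rolling protocol,
grid search and naive benchmarks."""
import numpy as np
import pandas as pd
import pytest

from szproject.forecast import (
    DatasetSplit,
    ModelOrder,
    apply_params,
    fit_model,
    grid_search,
    mse,
    naive_benchmarks,
    project,
    rolling_projection,
)


def _daily(values, start="2020-01-01"):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=pd.date_range(start, periods=len(values), freq="D"),
    )


def _ar1(phi, n, sigma=1.0, seed=0, mean=0.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0, sigma)
    return _daily(x + mean)


class TestModelOrder:
    def test_random_walk_allowed(self):
        assert ModelOrder(0, 1, 0).min_window == 2

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            ModelOrder(0, 0, 0)

    def test_paper_scale_order_constructible(self):
        o = ModelOrder(51, 1, 1, use_exog=True)
        assert o.min_window == 53 and str(o) == "ARIMAX(51,1,1)"


class TestForecastOracles:
    def test_ar1_closed_form(self):
        """h-step AR(1) forecast equals phi^h * x_t to 1e-8."""
        s = _ar1(0.7, 300, seed=1)
        fit = apply_params(s, None, ModelOrder(1, 0, 0), np.array([0.0, 0.7, 1.0]))
        proj = project(fit, horizon=14)
        expected = 0.7 ** np.arange(1, 15) * s.iloc[-1]
        assert np.abs(proj["point"].to_numpy() - expected).max() < 1e-8

    def test_random_walk_forecast_is_last_value(self):
        s = _daily(np.random.default_rng(2).normal(5, 1, 200).cumsum())
        fit = apply_params(s, None, ModelOrder(0, 1, 0), np.array([1.0]))
        proj = project(fit, horizon=14)
        assert np.array_equal(proj["point"].to_numpy(), np.full(14, s.iloc[-1]))

    def test_ma_forecast_reverts_to_mean_beyond_memory(self):
        s = _ar1(0.0, 300, seed=3)
        params = np.array([0.0, 0.4, 0.2, 1.0])  # intercept, ma1, ma2, sigma2
        fit = apply_params(s, None, ModelOrder(0, 0, 2), params)
        proj = project(fit, horizon=10)
        assert np.allclose(proj["point"].to_numpy()[2:], 0.0, atol=1e-10)

    def test_interval_widens_with_horizon(self):
        s = _ar1(0.7, 300, seed=4)
        fit = apply_params(s, None, ModelOrder(1, 0, 0), np.array([0.0, 0.7, 1.0]))
        proj = project(fit, horizon=14)
        widths = (proj["ci_high"] - proj["ci_low"]).to_numpy()
        assert (np.diff(widths) > -1e-12).all() and widths[-1] > widths[0]


class TestFit:
    def test_constant_series_degenerate_contract(self):
        s = _daily(np.full(120, 4.0))
        fit = fit_model(s, None, ModelOrder(1, 0, 0))
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-4)
        # implied unconditional mean ~ the constant
        implied = fit.intercept / max(1e-12, 1 - fit.ar_coefs[0])
        assert implied == pytest.approx(4.0, rel=0.05)

    def test_ar1_parameter_recovery(self):
        fit = fit_model(_ar1(0.7, 2000, seed=5), None, ModelOrder(1, 0, 0))
        assert 0.65 <= fit.ar_coefs[0] <= 0.75

    def test_exog_coefficient_recovery(self):
        rng = np.random.default_rng(6)
        n = 1000
        phase = rng.uniform(-np.pi, np.pi, n)
        sin = np.sin(phase)
        noise = np.zeros(n)
        for t in range(1, n):
            noise[t] = 0.5 * noise[t - 1] + rng.normal(0, 0.3)
        s = _daily(2.0 * sin + noise)
        exog = pd.DataFrame({"sin": sin}, index=s.index)
        fit = fit_model(s, exog, ModelOrder(1, 0, 0, use_exog=True))
        beta = fit.exog_coefs[0]
        names = fit.results.model.param_names
        se = np.sqrt(np.diag(fit.results.cov_params()))[names.index("x1")]
        assert abs(beta - 2.0) < 2 * se

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_model(_daily(np.ones(10)), None, ModelOrder(5, 1, 1))


class TestRolling:
    def test_residual_count_index_arithmetic(self):
        s = _ar1(0.5, 200, seed=7)
        rec = rolling_projection(s, None, ModelOrder(1, 0, 0), horizon=14, train_len=100)
        # one record per origin from train_len to n - horizon - 1
        assert len(rec) == 200 - 100 - 14
        assert rec["residual"].notna().all()
        assert (rec["target_date"] - rec["origin_date"] == pd.Timedelta(days=14)).all()

    def test_deterministic_series_zero_residuals(self):
        s = _daily(np.full(150, 2.5))
        rec = rolling_projection(
            s, None, ModelOrder(1, 0, 0), horizon=5, params=np.array([2.5, 0.0, 0.0]), train_len=50
        )
        assert np.abs(rec["residual"]).max() < 1e-10

    def test_white_noise_mean_model_residual_variance(self):
        rng = np.random.default_rng(8)
        s = _daily(rng.normal(0, 1, 800))
        rec = rolling_projection(
            s, None, ModelOrder(1, 0, 0), horizon=14,
            params=np.array([0.0, 0.0, 1.0]), train_len=100,
        )
        assert np.var(rec["residual"]) == pytest.approx(1.0, rel=0.15)

    def test_windowed_rolling_matches_per_origin_filtering(self):
        """Dual route: the convolution-based windowed rolling equals
        per-origin Kalman filtering on exactly the same trailing window."""
        rng = np.random.default_rng(9)
        n = 160
        s = _daily(np.cumsum(rng.normal(0, 0.1, n)) + 5)
        ex = pd.DataFrame(
            {"sin": np.sin(np.arange(n) / 7), "cos": np.cos(np.arange(n) / 7)}, index=s.index
        )
        order = ModelOrder(2, 1, 1, use_exog=True)
        W = 20
        fit = fit_model(s.iloc[:100], ex, order)
        fast = rolling_projection(
            s, ex, order, horizon=7, refit_policy="fixed", params=fit.params,
            train_len=100, window=W,
        )
        for k in (0, 10, 40):
            i = 100 + k
            f = apply_params(s.iloc[i + 1 - W : i + 1], ex.iloc[i + 1 - W : i + 1], order, fit.params)
            slow = project(f, ex.iloc[i + 1 : i + 8], horizon=7).iloc[6]
            assert fast["point"].iloc[k] == pytest.approx(slow["point"], abs=1e-7)
            assert fast["ci_low"].iloc[k] == pytest.approx(slow["ci_low"], abs=1e-6)

    def test_full_history_rolling_matches_per_origin_forecasts(self):
        """Dual route for the full-conditioning variant: the single-filter
        state recursion equals per-origin get_forecast."""
        rng = np.random.default_rng(10)
        n = 160
        s = _daily(np.cumsum(rng.normal(0, 0.1, n)) + 5)
        order = ModelOrder(2, 1, 1)
        fit = fit_model(s.iloc[:100], None, order)
        fast = rolling_projection(
            s, None, order, horizon=7, refit_policy="fixed_full", params=fit.params, train_len=100
        )
        for k in (0, 10, 40):
            i = 100 + k
            f = apply_params(s.iloc[: i + 1], None, order, fit.params)
            slow = project(f, horizon=7).iloc[6]
            assert fast["point"].iloc[k] == pytest.approx(slow["point"], abs=1e-10)
            assert fast["ci_low"].iloc[k] == pytest.approx(slow["ci_low"], abs=1e-8)

    def test_daily_refit_policy_runs(self):
        s = _ar1(0.6, 140, seed=10, mean=3.0)
        rec = rolling_projection(
            s, None, ModelOrder(1, 0, 0), horizon=7, refit_policy="daily",
            train_len=100, window=60,
        )
        assert len(rec) and rec["residual"].notna().any()


class TestMSE:
    def test_zero_residuals(self):
        rec = pd.DataFrame({"residual": [0.0, 0.0], "observed": [1, 1]})
        assert mse(rec) == 0.0

    @pytest.mark.parametrize(
        "resid, expected", [([1.0, -1.0], 1.0), ([0.3], 0.09), ([2.0, 0.0], 2.0)]
    )
    def test_arithmetic(self, resid, expected):
        rec = pd.DataFrame({"residual": resid, "observed": np.ones(len(resid))})
        assert mse(rec) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse(pd.DataFrame({"residual": [np.nan], "observed": [np.nan]}))


class TestGridSearch:
    def test_singleton_grid(self):
        s = _ar1(0.5, 200, seed=11)
        best, table = grid_search(s, None, [ModelOrder(1, 0, 0)], n_iter=3, seed=0)
        assert best == ModelOrder(1, 0, 0)
        assert len(table) == 1

    def test_reproducible_score_table(self):
        s = _ar1(0.5, 250, seed=12)
        grid = [ModelOrder(1, 0, 0), ModelOrder(0, 1, 0)]
        _, t1 = grid_search(s, None, grid, n_iter=5, seed=4)
        _, t2 = grid_search(s, None, grid, n_iter=5, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_order_recovery_differenced_ar(self):
        """Data from an integrated AR(2) should prefer d=1 with p>=2 in a
        majority of seeds."""
        wins = 0
        grid = [ModelOrder(1, 0, 0), ModelOrder(1, 1, 0), ModelOrder(2, 1, 0)]
        for seed in range(7):
            rng = np.random.default_rng(100 + seed)
            n = 300
            z = np.zeros(n)
            for t in range(2, n):
                z[t] = 0.6 * z[t - 1] - 0.3 * z[t - 2] + rng.normal()
            s = _daily(np.cumsum(z))
            best, _ = grid_search(s, None, grid, n_iter=8, horizon=7, seed=seed)
            wins += best.d == 1 and best.p >= 2
        assert wins >= 4


class TestNaiveBenchmarks:
    def test_constant_series_zero_mse(self):
        s = _daily(np.full(200, 3.0))
        out = naive_benchmarks(s, horizon=7, train_len=100)
        for rec in out.values():
            assert mse(rec) == pytest.approx(0.0, abs=1e-6)

    def test_ar1_data_favours_ar1_model(self):
        wins = 0
        for seed in range(5):
            s = _ar1(0.8, 400, seed=200 + seed)
            out = naive_benchmarks(s, horizon=7, train_len=200)
            wins += mse(out["AR(1)"]) <= mse(out["MA(5)"])
        assert wins >= 3

    def test_random_walk_mse_grows_with_horizon(self):
        rng = np.random.default_rng(13)
        s = _daily(np.cumsum(rng.normal(0, 1, 500)))
        errs = []
        for h in (1, 5, 14):
            out = naive_benchmarks(s, horizon=h, train_len=250)
            errs.append(mse(out["MA(5)"]))
        assert errs[0] < errs[1] < errs[2]


class TestIntervalCalibration:
    def test_one_step_coverage_on_gaussian_ar1(self):
        """Empirical 95% interval coverage at h=1 lies in [0.92, 0.97]."""
        hits = total = 0
        for seed in range(10):
            s = _ar1(0.6, 400, seed=300 + seed)
            rec = rolling_projection(
                s, None, ModelOrder(1, 0, 0), horizon=1,
                params=np.array([0.0, 0.6, 1.0]), train_len=100,
            )
            inside = (rec["observed"] >= rec["ci_low"]) & (rec["observed"] <= rec["ci_high"])
            hits += int(inside.sum())
            total += len(rec)
        assert 0.92 <= hits / total <= 0.97
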