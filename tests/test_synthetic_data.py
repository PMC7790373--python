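import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lagcv import SimulationConfig, simulate, simulate_environment, simulate_mortality
from lagcv.synthetic_data import (
    cross_basis,
    natural_cubic_basis,
    seasonal_spline,
    true_design,
)


class TestEnvironment:
    def test_noiseless_environment_is_a_pure_sinusoid(self):
        cfg = SimulationConfig(
            n_days=365,
            temp_sigma=0.0,
            o3_temp_coupling=0.0,
            o3_shared=0.0,
            o3_sigma=0.0,
            pm25_temp_coupling=0.0,
            pm25_shared=0.0,
            pm25_sigma=0.0,
        )
        env = simulate_environment(cfg)
        f = env.frame
        doy = f.index.dayofyear.to_numpy(dtype=float)
        expected = cfg.temp_mean + cfg.temp_amplitude * np.cos(
            2 * np.pi * (doy - cfg.temp_peak_day) / 365.25
        )
        np.testing.assert_allclose(f["temperature"].to_numpy(), expected, atol=1e-12)
        assert f["o3"].nunique() == 1 and f["pm25"].nunique() == 1

    def test_same_seed_same_series(self):
        a = simulate_environment(SimulationConfig(n_days=200, seed=9))
        b = simulate_environment(SimulationConfig(n_days=200, seed=9))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_default_temperature_autocorrelation_exceeds_half(self):
        env = simulate_environment(SimulationConfig(n_days=1818, seed=2))
        t = env.frame["temperature"].to_numpy()
        r1 = np.corrcoef(t[:-1], t[1:])[0, 1]
        assert r1 > 0.5


class TestCrossBasis:
    def test_column_count_is_vx_times_vl(self):
        rng = np.random.default_rng(0)
        cb = cross_basis(rng.uniform(10, 30, 200), max_lag=30)
        assert cb.temp_basis.n_basis == 5  # quadratic B-spline, 3 interior knots
        assert cb.lag_basis.n_basis == 5  # natural cubic + intercept, 3 interior
        assert cb.matrix.shape[1] == 25
        assert cb.valid.sum() == 200 - 30

    @pytest.mark.parametrize("max_lag,n", [(1, 6), (2, 8), (3, 10)])
    def test_rows_equal_brute_force_double_sum(self, max_lag, n):
        rng = np.random.default_rng(max_lag)
        x = rng.uniform(5, 33, n)
        cb = cross_basis(x, max_lag=max_lag)
        T = cb.temp_basis.evaluate(x)
        L = cb.lag_basis.evaluate(np.arange(max_lag + 1))
        v_l = L.shape[1]
        for t in range(max_lag, n):
            for i in range(T.shape[1]):
                for j in range(v_l):
                    brute = sum(T[t - k, i] * L[k, j] for k in range(max_lag + 1))
                    assert cb.matrix[t, i * v_l + j] == pytest.approx(brute, abs=1e-12)

    def test_constant_exposure_identity(self):
        x0 = 20.0
        cb = cross_basis(
            np.full(12, x0), max_lag=3, temp_knots=(12.0, 22.0, 28.0), temp_boundary=(5.0, 33.0)
        )
        tb_row = cb.temp_basis.evaluate([x0])[0]
        lag_sums = cb.lag_basis.evaluate(np.arange(4)).sum(axis=0)
        expected = np.kron(tb_row, lag_sums)
        for t in range(3, 12):
            np.testing.assert_allclose(cb.matrix[t], expected, atol=1e-12)

    def test_linearity_in_coefficients(self):
        rng = np.random.default_rng(4)
        cb = cross_basis(rng.uniform(10, 30, 100), max_lag=10)
        b1, b2 = rng.normal(size=25), rng.normal(size=25)
        np.testing.assert_allclose(
            cb.matrix @ (b1 + b2), cb.matrix @ b1 + cb.matrix @ b2, atol=1e-9
        )

    def test_too_few_distinct_temperatures_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cross_basis(np.full(50, 20.0), max_lag=3)


class TestSeasonalSpline:
    def test_five_year_span_has_40_columns(self):
        dates = pd.date_range("2012-01-01", "2016-12-31", freq="D")
        basis = seasonal_spline(dates, df_per_year=8)
        assert basis.shape == (len(dates), 40)
        assert np.all(np.isfinite(basis))

    def test_columns_are_smooth_in_the_day_index(self):
        dates = pd.date_range("2012-01-01", "2013-12-31", freq="D")
        basis = seasonal_spline(dates)
        jumps = np.abs(np.diff(basis, axis=0)).max()
        scale = np.abs(basis).max()
        assert jumps < 0.05 * scale

    def test_reproduces_a_cubic_trend_in_the_interior(self):
        dates = pd.date_range("2012-01-01", periods=1818, freq="D")
        basis = seasonal_spline(dates)
        x = np.arange(1818.0) / 1000
        cubic = 1 + 2 * x - 3 * x**2 + 0.5 * x**3
        design = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(design, cubic, rcond=None)
        resid = np.abs(design @ coef - cubic)
        assert resid[91:-91].max() < 1e-3

    def test_sub_year_span_rejected(self):
        with pytest.raises(ValueError):
            seasonal_spline(pd.date_range("2012-01-01", periods=120, freq="D"))


class TestNaturalCubicBasis:
    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 2.0, 5.0, 8.0, 10.0])
        x = np.linspace(-5, 15, 400)
        basis = natural_cubic_basis(x, knots, include_intercept=True)
        for col in basis.T:
            left = col[x < -1]
            d2 = np.diff(left, 2)
            assert np.abs(d2).max() < 1e-9
            right = col[x > 11]
            assert np.abs(np.diff(right, 2)).max() < 1e-9


class TestMortality:
    def test_null_model_is_iid_poisson(self):
        cfg = SimulationConfig(
            n_days=2000,
            alpha=float(np.log(60.0)),
            beta=tuple(np.zeros(25)),
            beta_o3=0.0,
            beta_pm25=0.0,
            seasonal_amplitude=0.0,
            seed=12,
        )
        series = simulate(cfg)
        d = series.frame["death"].to_numpy()
        assert abs(d.mean() - 60.0) < 3 * np.sqrt(60.0 / len(d))
        # Poisson mean-variance identity within Monte-Carlo tolerance
        assert d.var() / d.mean() == pytest.approx(1.0, abs=0.15)

    def test_burn_in_rows_have_covariates_but_no_deaths(self):
        cfg = SimulationConfig(n_days=400, seed=1)
        env = simulate_environment(cfg)
        kept = simulate_mortality(env, cfg, keep_burn_in=True)
        assert kept.n_days == 400
        head = kept.frame.iloc[:30]
        assert head["death"].isna().all()
        assert head["temperature"].notna().all()
        dropped = simulate_mortality(env, cfg)
        assert dropped.n_days == 370
        assert dropped.frame["death"].notna().all()

    def test_increasing_ozone_coefficient_raises_every_mean(self):
        cfg = SimulationConfig(n_days=400, seed=3)
        env = simulate_environment(cfg, n_days=430)
        d1, c1, _ = true_design(env, cfg)
        d2, c2, _ = true_design(env, cfg.replace(beta_o3=2 * cfg.beta_o3))
        eta1 = d1.to_numpy() @ c1
        eta2 = d2.to_numpy() @ c2
        o3_dev = d1["o3"].to_numpy()
        assert np.all(np.sign(eta2 - eta1) == np.sign(o3_dev * cfg.beta_o3))

    def test_coefficient_blowup_names_the_scale(self):
        with pytest.raises(ValueError, match="plausible"):
            SimulationConfig(n_days=400, alpha=25.0)
        cfg = SimulationConfig(n_days=400, seasonal_amplitude=50.0)
        with pytest.raises(ValueError, match="coefficient"):
            simulate(cfg)

    def test_glm_on_true_design_recovers_parameters_smoke(self):
        """Single-replicate version of the full recovery study."""
        cfg = SimulationConfig(n_days=1818, seed=17)
        env = simulate_environment(
            cfg.replace(start="2011-12-02"), n_days=cfg.n_days + cfg.max_lag
        )
        series = simulate_mortality(env, cfg, keep_burn_in=True)
        design, coefs, valid = true_design(env, cfg)
        y = series.frame["death"].to_numpy()[valid]
        fit = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        ci = fit.conf_int()
        for name, truth in (
            ("const", cfg.alpha),
            ("o3", cfg.beta_o3),
            ("pm25", cfg.beta_pm25),
        ):
            lo, hi = ci.loc[name]
            assert lo <= truth <= hi, f"{name}: {truth} outside [{lo}, {hi}]"
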