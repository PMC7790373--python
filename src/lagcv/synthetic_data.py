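"""DLNM-structured synthetic daily series.

Generates seasonal, autocorrelated temperature, temperature-coupled
pollutants, and Poisson daily death counts whose log-mean follows the
distributed-lag nonlinear model

    log(mu_t) = alpha + s(x_t, l; beta) + b_O3 * O3_t + b_PM * PM2.5_t
                + f(t; theta)

where s is the cross-basis lag-temperature surface (quadratic B-spline in
temperature with interior knots at the 10th/75th/90th percentiles, natural
cubic spline in lag with 5 df and three interior knots equally spaced on
the log-lag scale, maximum lag 30) and f is a natural cubic seasonal
spline with 8 df per year.

Default scales emulate the Taipei 2012-2016 series the model was built
for: ~61 deaths/day, temperature ~23.6 +/- 5.5 C, O3 ~28 ppb,
PM2.5 ~20 ug/m3, and a day-to-day temperature autocorrelation well above
0.5.  These are steering targets for realism, not assertions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .io_timeseries import DailySeries

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# spline bases


def natural_cubic_basis(
    x: np.ndarray, knots: np.ndarray, include_intercept: bool = False
) -> np.ndarray:
    """Natural cubic spline basis with the given knot sequence.

    ``knots`` includes the boundary knots; with K knots the basis spans K
    functions (intercept included) or K - 1 (excluded).  The classic
    truncated-power construction: N1 = 1, N2 = x,
    N_{k+2} = d_k - d_{K-1} with d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3]
    / (t_K - t_k), which is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    if len(t) < 3 or len(np.unique(t)) != len(t):
        raise ValueError("need >= 3 distinct knots")

    def d(k):
        return (
            np.clip(x - t[k], 0, None) ** 3 - np.clip(x - t[-1], 0, None) ** 3
        ) / (t[-1] - t[k])

    cols = [np.ones_like(x), x]
    d_last = d(len(t) - 2)
    for k in range(len(t) - 2):
        cols.append(d(k) - d_last)
    basis = np.column_stack(cols)
    return basis if include_intercept else basis[:, 1:]


@dataclass(frozen=True)
class TemperatureBasis:
    """Quadratic B-spline in temperature, interior knots at data percentiles."""

    internal_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 2

    @property
    def n_basis(self) -> int:
        # full B-spline basis minus the dropped intercept column
        return len(self.internal_knots) + self.degree

    def evaluate(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.boundary)
        lo, hi = self.boundary
        t = np.r_[[lo] * (self.degree + 1), self.internal_knots, [hi] * (self.degree + 1)]
        full = BSpline.design_matrix(x, t, self.degree).toarray()
        return full[:, 1:]  # drop one column: basis without intercept


@dataclass(frozen=True)
class LagBasis:
    """Natural cubic spline in lag with an intercept column.

    Interior knots sit at exp of equally spaced points between log(1) and
    log(max_lag); boundary knots at 0 and max_lag.
    """

    max_lag: int
    n_internal: int = 3

    @property
    def knots(self) -> np.ndarray:
        interior = np.exp(
            np.linspace(0.0, np.log(self.max_lag), self.n_internal + 2)[1:-1]
        )
        return np.unique(np.r_[0.0, interior, float(self.max_lag)])

    @property
    def n_basis(self) -> int:
        return len(self.knots) if len(self.knots) >= 3 else 2

    def evaluate(self, lags) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        if len(self.knots) < 3:  # max_lag <= 2: knots degenerate, use linear
            return np.column_stack([np.ones_like(lags), lags])
        return natural_cubic_basis(lags, self.knots, include_intercept=True)


@dataclass(frozen=True)
class CrossBasis:
    """n x (v_x * v_l) matrix encoding the lag-temperature surface.

    Row t (valid for t >= max_lag) holds, for each pair (i, j),
    sum_k T_i(x_{t-k}) * L_j(k) over k = 0..max_lag.  Rows without a full
    lag history are zero and flagged invalid.
    """

    matrix: np.ndarray
    valid: np.ndarray
    temp_basis: TemperatureBasis
    lag_basis: LagBasis
    max_lag: int

    @property
    def n_columns(self) -> int:
        return self.temp_basis.n_basis * self.lag_basis.n_basis

    @property
    def column_names(self) -> list[str]:
        return [
            f"cb_t{i}_l{j}"
            for i in range(self.temp_basis.n_basis)
            for j in range(self.lag_basis.n_basis)
        ]


def cross_basis(
    temperature,
    max_lag: int = 30,
    temp_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0),
    lag_internal_knots: int = 3,
    temp_knots: tuple[float, ...] | None = None,
    temp_boundary: tuple[float, float] | None = None,
) -> CrossBasis:
    """Build the cross-basis matrix for a temperature series.

    Interior temperature knots default to data percentiles; pass
    ``temp_knots``/``temp_boundary`` to place them explicitly (required
    e.g. for a constant exposure series, where percentiles degenerate).
    """
    x = np.asarray(temperature, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError("series must be longer than max_lag")
    if temp_knots is not None:
        internal = tuple(float(k) for k in temp_knots)
        boundary = temp_boundary or (min(x.min(), internal[0]) - 1.0, max(x.max(), internal[-1]) + 1.0)
    else:
        if len(np.unique(x)) <= len(temp_knot_percentiles):
            raise ValueError("fewer distinct temperatures than knots")
        internal = tuple(np.percentile(x, temp_knot_percentiles))
        boundary = (float(x.min()), float(x.max()))
    tb = TemperatureBasis(internal_knots=internal, boundary=boundary)
    lb = LagBasis(max_lag=max_lag, n_internal=lag_internal_knots)

    T = tb.evaluate(x)  # (n, v_x)
    L = lb.evaluate(np.arange(max_lag + 1))  # (max_lag+1, v_l)
    v_x, v_l = T.shape[1], L.shape[1]
    M = np.zeros((n, v_x * v_l))
    for k in range(max_lag + 1):
        shifted = T[max_lag - k : n - k]  # T_i(x_{t-k}) for t >= max_lag
        M[max_lag:] += (shifted[:, :, None] * L[k][None, None, :]).reshape(
            n - max_lag, v_x * v_l
        )
    valid = np.zeros(n, dtype=bool)
    valid[max_lag:] = True
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite cross-basis entries")
    return CrossBasis(matrix=M, valid=valid, temp_basis=tb, lag_basis=lb, max_lag=max_lag)


def seasonal_spline(dates: pd.DatetimeIndex, df_per_year: int = 8) -> np.ndarray:
    """Natural cubic seasonal basis over the sequential day index.

    Total degrees of freedom (excluding intercept) = df_per_year x number
    of calendar years in the span; boundary knots at the series ends,
    interior knots equally spaced in the day index.
    """
    dates = pd.DatetimeIndex(dates)
    n = len(dates)
    if n < 2 or (dates[-1] - dates[0]).days < 364:
        raise ValueError("need at least one year of dates")
    n_years = dates.year.nunique()
    df_total = df_per_year * n_years
    idx = np.arange(n, dtype=float)
    knots = np.linspace(0.0, n - 1.0, df_total + 1)
    return natural_cubic_basis(idx, knots, include_intercept=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults emulate Taipei 2012-2016."""

    n_days: int = 1818
    start: str = "2012-01-01"
    max_lag: int = 30
    seed: int = 0
    # temperature: annual sinusoid + AR(1) noise
    temp_mean: float = 23.6
    temp_amplitude: float = 6.5
    temp_peak_day: int = 197  # mid-July
    temp_rho: float = 0.7
    temp_sigma: float = 2.2  # innovation SD of the AR(1) component
    # pollutants: base + temperature coupling + shared and private noise
    o3_mean: float = 28.0
    o3_temp_coupling: float = 0.9
    o3_shared: float = 3.0
    o3_sigma: float = 6.0
    pm25_mean: float = 20.5
    pm25_temp_coupling: float = -0.6
    pm25_shared: float = 4.0
    pm25_sigma: float = 7.0
    # outcome model
    alpha: float = 4.117  # log(61.4) baseline deaths/day
    beta: tuple[float, ...] | None = None  # None -> default U-shaped surface
    cold_effect: float = 0.12  # cumulative log-RR of sustained cold
    heat_effect: float = 0.10  # cumulative log-RR of sustained heat
    beta_o3: float = 0.0012
    beta_pm25: float = 0.0015
    seasonal_amplitude: float = 0.09  # log-scale winter excess
    seasonal_peak_day: int = 15  # mid-January
    df_per_year: int = 8
    eta_cap: float = 20.0
    temp_knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)

    def __post_init__(self) -> None:
        if self.n_days <= self.max_lag:
            raise ValueError("n_days must exceed max_lag")
        if not 0 < np.exp(self.alpha) < 1e6:
            raise ValueError("exp(alpha) outside a plausible daily count range")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# environment


def simulate_environment(config: SimulationConfig, n_days: int | None = None) -> DailySeries:
    """Seasonal autocorrelated temperature and coupled pollutants (no deaths)."""
    n = n_days if n_days is not None else config.n_days
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    seasonal = config.temp_amplitude * np.cos(
        2 * np.pi * (doy - config.temp_peak_day) / DAYS_PER_YEAR
    )
    ar = np.zeros(n)
    eps = rng.normal(0.0, config.temp_sigma, size=n)
    for t in range(1, n):
        ar[t] = config.temp_rho * ar[t - 1] + eps[t]
    temp = config.temp_mean + seasonal + ar

    shared = rng.normal(0.0, 1.0, size=n)
    dev = temp - config.temp_mean
    o3 = (
        config.o3_mean
        + config.o3_temp_coupling * dev
        + config.o3_shared * shared
        + rng.normal(0.0, config.o3_sigma, size=n)
    )
    pm25 = (
        config.pm25_mean
        + config.pm25_temp_coupling * dev
        + config.pm25_shared * shared
        + rng.normal(0.0, config.pm25_sigma, size=n)
    )
    frame = pd.DataFrame(
        {
            "temperature": temp,
            "o3": np.clip(o3, 0.0, None),
            "pm25": np.clip(pm25, 0.0, None),
        },
        index=dates,
    )
    frame.index.name = "date"
    return DailySeries(frame=frame)


# ---------------------------------------------------------------------------
# outcome model


def default_beta(cb: CrossBasis, config: SimulationConfig) -> np.ndarray:
    """U-shaped cumulative temperature-mortality surface.

    Cold excess loads on the low-temperature basis functions and is spread
    over long lags; heat excess loads on the high-temperature functions and
    concentrates at short lags.  Lag profiles (normalized to sum 1 over
    k = 0..max_lag) are projected onto the lag basis by least squares, so a
    sustained extreme temperature contributes roughly cold_effect /
    heat_effect to the log-rate cumulatively.
    """
    v_x = cb.temp_basis.n_basis
    k = np.arange(cb.max_lag + 1, dtype=float)
    L = cb.lag_basis.evaluate(k)

    def project(curve):
        curve = curve / curve.sum()
        coef, *_ = np.linalg.lstsq(L, curve, rcond=None)
        return coef

    cold_lag = project(np.exp(-k / 15.0))  # distributed over weeks
    heat_lag = project(np.exp(-k / 2.0))  # mostly immediate
    w_cold = np.zeros(v_x)
    w_cold[0] = 1.0
    w_cold[1] = 0.3
    w_heat = np.zeros(v_x)
    w_heat[-1] = 1.0
    w_heat[-2] = 0.3
    beta = config.cold_effect * np.kron(w_cold, cold_lag) + config.heat_effect * np.kron(
        w_heat, heat_lag
    )
    return beta


def true_design(
    environment: DailySeries, config: SimulationConfig
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """The exact (centered) design and coefficients behind the simulator.

    Returns ``(design, coefficients, valid_mask)`` where ``design`` has an
    intercept column followed by centered cross-basis, pollutant and
    seasonal-spline columns over the valid (full-lag-history) days, and
    ``design @ coefficients`` is the true log-mean.  This is the design a
    log-linear count regression should recover the parameters from.
    """
    f = environment.frame
    cb = cross_basis(
        f["temperature"].to_numpy(),
        max_lag=config.max_lag,
        temp_knot_percentiles=config.temp_knot_percentiles,
    )
    valid = cb.valid
    dates = f.index[valid]

    cb_m = cb.matrix[valid]
    seas = seasonal_spline(dates, df_per_year=config.df_per_year)
    o3 = f["o3"].to_numpy()[valid]
    pm25 = f["pm25"].to_numpy()[valid]

    def center(a):
        return a - a.mean(axis=0)

    beta = (
        np.asarray(config.beta, dtype=float)
        if config.beta is not None
        else default_beta(cb, config)
    )
    if beta.size != cb.n_columns:
        raise ValueError(
            f"beta has {beta.size} entries, cross-basis needs {cb.n_columns}"
        )

    # theta: least-squares projection of a winter-peaked cosine on the basis
    doy = dates.dayofyear.to_numpy(dtype=float)
    target = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_day) / DAYS_PER_YEAR
    )
    seas_c = center(seas)
    theta, *_ = np.linalg.lstsq(seas_c, target - target.mean(), rcond=None)

    cols = {"const": np.ones(valid.sum())}
    cols.update(dict(zip(cb.column_names, center(cb_m).T)))
    cols["o3"] = center(o3)
    cols["pm25"] = center(pm25)
    cols.update({f"seas_{j:02d}": c for j, c in enumerate(seas_c.T)})
    design = pd.DataFrame(cols, index=dates)
    coefs = np.r_[config.alpha, beta, config.beta_o3, config.beta_pm25, theta]
    return design, coefs, valid


def simulate_mortality(
    environment: DailySeries, config: SimulationConfig, keep_burn_in: bool = False
) -> DailySeries:
    """Draw Poisson deaths from the DLNM log-mean over the environment.

    The first ``max_lag`` days lack a full lag history; by default they are
    dropped so every returned row is complete.  With ``keep_burn_in=True``
    they are kept carrying covariates but no simulated deaths.
    """
    design, coefs, valid = true_design(environment, config)
    eta = design.to_numpy() @ coefs
    if np.max(np.abs(eta)) > config.eta_cap:
        raise ValueError(
            "log-mean exceeds the cap: check alpha/beta/seasonal coefficient scales"
        )
    rng = np.random.default_rng(config.seed + 1)  # offset: environment used seed
    deaths_valid = rng.poisson(np.exp(eta)).astype(float)

    frame = environment.frame.copy()
    death = np.full(len(frame), np.nan)
    death[valid] = deaths_valid
    frame.insert(0, "death", death)
    if not keep_burn_in:
        frame = frame.iloc[config.max_lag :]
    return DailySeries(frame=frame)


def simulate(config: SimulationConfig) -> DailySeries:
    """Convenience: environment + mortality with exactly n_days complete rows.

    The environment is simulated for ``n_days + max_lag`` days starting
    ``max_lag`` days before ``config.start``, so the burn-in needed by the
    lag structure neither shortens nor shifts the output.
    """
    early = (pd.Timestamp(config.start) - pd.Timedelta(days=config.max_lag)).strftime(
        "%Y-%m-%d"
    )
    env = simulate_environment(
        config.replace(start=early), n_days=config.n_days + config.max_lag
    )
    return simulate_mortality(env, config, keep_burn_in=False)
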