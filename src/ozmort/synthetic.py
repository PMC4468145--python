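"""Synthetic city series with known exposure-response structure.

The generator emulates the statistical structure the analysis assumes:
seasonal temperature with AR(1) weather noise, ozone linearly linked to
temperature (a photochemistry proxy) plus AR(1) noise floored at zero,
lognormal PM10 correlated with ozone, bounded humidity, and Poisson
death counts whose log-rate contains a long-term trend, season,
day-of-week and holiday effects, a U-shaped temperature term, a linear
PM10 term, and an ozone term that is absent, linear, or piecewise linear
(hockey stick) with a known threshold. The ozone effect acts on the
lag0-1 moving average so the generative lag matches the default
analysis lag.

Every draw is deterministic given (seed, city_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import CitySeries


@dataclass
class ExposureEffect:
    """Ozone term of the generative log-rate.

    kind: 'none', 'linear' (slope per ppb) or 'hockey'
    (threshold t_star ppb with separate slopes below/above).
    """

    kind: str = "none"
    slope: float = 0.0
    t_star: float = 25.0
    slope_below: float = 0.0
    slope_above: float = 0.0

    @classmethod
    def none(cls):
        return cls(kind="none")

    @classmethod
    def linear(cls, slope):
        return cls(kind="linear", slope=slope)

    @classmethod
    def hockey(cls, t_star, slope_below, slope_above):
        return cls(kind="hockey", t_star=t_star,
                   slope_below=slope_below, slope_above=slope_above)

    def log_rate(self, o3: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(o3)
        if self.kind == "linear":
            return self.slope * o3
        if self.kind == "hockey":
            return (self.slope_below * np.minimum(o3, self.t_star)
                    + self.slope_above * np.maximum(o3 - self.t_star, 0.0))
        raise ValueError(f"unknown exposure effect kind {self.kind!r}")


@dataclass
class SyntheticConfig:
    """Scenario description for :func:`simulate_city`.

    Default scale mimics a mid-size metropolitan study city: two million
    persons and a baseline log-rate giving roughly 55 deaths/day. Temperature follows an
    annual sinusoid (mean 14 degC, amplitude 10) with AR(1) noise; ozone
    targets mean 25 ppb / sd 12 ppb with correlation about 0.6 to
    temperature; PM10 is lognormal (median ~46 ug/m3) correlated with
    ozone. The temperature confounder is quadratic (U-shaped) around
    20 degC so spline adjustment is non-trivially exercised.
    """

    n_cities: int = 1
    n_days: int = 3652
    start_date: str = "2000-01-01"
    beta0: float = -10.5                      # log deaths/person/day; ~55/day at 2e6
    population: float = 2.0e6
    population_drift: float = 0.0             # persons/year, linear
    temp_mean: float = 14.0
    temp_amplitude: float = 10.0
    temp_phase_day: int = 197                 # annual peak mid-July
    ar_coef: float = 0.7
    ar_sd: float = 2.0                        # innovation sd of temperature AR(1)
    o3_target_mean: float = 25.0
    o3_target_sd: float = 12.0
    o3_temp_corr: float = 0.6
    pm10_mean: float = 50.0
    pm10_sd: float = 30.0
    pm10_o3_corr: float = 0.4
    rh_mean: float = 63.0
    rh_sd: float = 13.0
    temp_quad_coef: float = 0.0003            # log-rate per (degC - 20)^2
    pm10_coef: float = 0.0002                 # log-rate per ug/m3
    dow_effects: tuple = (0.0, -0.005, -0.005, 0.0, 0.005, 0.01, 0.015)  # Mon..Sun
    holiday_effect: float = 0.02
    warm_season_effect: float = -0.03
    trend_slope: float = -2.0e-5              # log-rate per day
    n_holidays_per_year: int = 15
    city_intercept_sd: float = 0.0            # between-city heterogeneity
    exposure: ExposureEffect = field(default_factory=ExposureEffect.none)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_days < 730:
            problems.append("n_days must be >= 730 (two full years)")
        for name in ("ar_sd", "o3_target_sd", "pm10_sd", "rh_sd", "city_intercept_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.population <= 0:
            problems.append("population must be > 0")
        if self.exposure.kind == "hockey":
            lo = 0.0
            hi = self.o3_target_mean + 4 * self.o3_target_sd
            if not (lo < self.exposure.t_star < hi):
                problems.append("hockey threshold t_star outside plausible o3 range")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    def replace(self, **kw) -> "SyntheticConfig":
        d = asdict(self)
        exp = d.pop("exposure")
        cfg = SyntheticConfig(**{**d, **{k: v for k, v in kw.items() if k != "exposure"}},
                              exposure=kw.get("exposure", ExposureEffect(**exp)))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        exp = d.pop("exposure", None)
        if "dow_effects" in d:
            d["dow_effects"] = tuple(d["dow_effects"])
        return cls(exposure=ExposureEffect(**exp) if exp else ExposureEffect.none(), **d)


def _ar1(rng, n, coef, innov_sd):
    """Stationary AR(1) path."""
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    stat_sd = innov_sd / np.sqrt(1 - coef**2) if abs(coef) < 1 else innov_sd
    x[0] = rng.normal(0.0, stat_sd)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + e[t]
    return x


def simulate_city(cfg: SyntheticConfig, city_index: int = 0) -> CitySeries:
    """Draw one synthetic :class:`CitySeries`, deterministic in (seed, city_index)."""
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed) % (2**31), int(city_index)])
    n = cfg.n_days
    dates = pd.date_range(cfg.start_date, periods=n, freq="D")
    doy = dates.dayofyear.values.astype(float)

    # --- weather -------------------------------------------------------
    season = np.cos(2 * np.pi * (doy - cfg.temp_phase_day) / 365.25)
    temp = cfg.temp_mean + cfg.temp_amplitude * season + _ar1(rng, n, cfg.ar_coef, cfg.ar_sd)

    # ozone: linear in temperature plus AR(1) noise, floored at 0, scaled
    # so that mean/sd hit their targets before flooring
    temp_sd = np.sqrt(cfg.temp_amplitude**2 / 2 + cfg.ar_sd**2 / (1 - cfg.ar_coef**2))
    b = cfg.o3_temp_corr * cfg.o3_target_sd / temp_sd
    resid_sd = cfg.o3_target_sd * np.sqrt(max(1 - cfg.o3_temp_corr**2, 0.0))
    o3_noise = _ar1(rng, n, 0.5, resid_sd * np.sqrt(1 - 0.5**2))
    o3 = cfg.o3_target_mean + b * (temp - cfg.temp_mean) + o3_noise
    o3 = np.maximum(o3, 0.0)

    # PM10: lognormal, correlated with ozone through its standard score
    sigma = np.sqrt(np.log1p((cfg.pm10_sd / cfg.pm10_mean) ** 2))
    mu_ln = np.log(cfg.pm10_mean) - sigma**2 / 2
    z_o3 = (o3 - o3.mean()) / max(o3.std(), 1e-12)
    z = cfg.pm10_o3_corr * z_o3 + np.sqrt(1 - cfg.pm10_o3_corr**2) * rng.standard_normal(n)
    pm10 = np.exp(mu_ln + sigma * z)

    rh = np.clip(cfg.rh_mean + 5 * season + rng.normal(0, cfg.rh_sd, n), 0.0, 100.0)

    # --- calendar ------------------------------------------------------
    dow = dates.dayofweek.values
    warm = ((dates.month >= 4) & (dates.month <= 9)).astype(float)
    holiday = np.zeros(n)
    holiday[doy == 1] = 1.0  # New Year
    extra = rng.choice(n, size=cfg.n_holidays_per_year * max(n // 365, 1), replace=False)
    holiday[extra] = 1.0

    # --- population ----------------------------------------------------
    years = dates.year
    year0 = years[0]
    pop_by_year = {
        int(y): cfg.population + cfg.population_drift * (int(y) - int(year0))
        for y in np.unique(years)
    }
    pop_daily = np.array([pop_by_year[int(y)] for y in years])

    # --- log-rate ------------------------------------------------------
    o3_lag01 = o3.copy()
    o3_lag01[1:] = (o3[1:] + o3[:-1]) / 2.0  # day 0 uses its own value
    city_icept = (rng.normal(0.0, cfg.city_intercept_sd)
                  if cfg.city_intercept_sd > 0 else 0.0)
    log_rate = (
        np.log(pop_daily)
        + cfg.beta0
        + city_icept
        + cfg.trend_slope * np.arange(n)
        + cfg.warm_season_effect * warm
        + np.asarray(cfg.dow_effects)[dow]
        + cfg.holiday_effect * holiday
        + cfg.temp_quad_coef * (temp - 20.0) ** 2
        + cfg.pm10_coef * pm10
        + cfg.exposure.log_rate(o3_lag01)
    )
    deaths = rng.poisson(np.exp(log_rate)).astype(float)

    data = pd.DataFrame(
        {
            "deaths_all": deaths,
            # cause-specific counts by binomial thinning (keeps them Poisson)
            "deaths_cvd": rng.binomial(deaths.astype(int), 0.25).astype(float),
            "deaths_resp": rng.binomial(deaths.astype(int), 0.10).astype(float),
            "o3_mean": o3,
            "o3_max1h": o3 * 1.5,
            "pm10": pm10,
            "temp": temp,
            "rh": rh,
            "holiday": holiday,
        },
        index=dates,
    )
    return CitySeries(
        city_id=f"synth-{city_index:02d}", country="synthetic",
        data=data, population=pop_by_year,
    )


def simulate_study(cfg: SyntheticConfig):
    """All cities of a scenario: list of CitySeries, one per city_index."""
    return [simulate_city(cfg, i) for i in range(cfg.n_cities)]


# ----------------------------------------------------------------------
@dataclass
class RecoveryReport:
    """Aggregate of repeated full-pipeline runs on synthetic truth."""

    n_reps: int
    t_true: float | None
    t_hat: np.ndarray              # NaN where the rule did not fire / no search
    ci_low: np.ndarray
    ci_high: np.ndarray
    meets_criteria: np.ndarray     # bool per rep
    delta_aic: np.ndarray
    bias: float
    rmse: float
    coverage: float                # share of CIs containing t_true
    criteria_rate: float

    def summary(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "t_true": self.t_true,
            "bias": self.bias,
            "rmse": self.rmse,
            "coverage": self.coverage,
            "criteria_rate": self.criteria_rate,
        }


def recovery_experiment(cfg: SyntheticConfig, n_reps: int, B_bootstrap: int = 0,
                        run_search: bool = True, spec=None,
                        grid=None) -> RecoveryReport:
    """Run the full city-specific pipeline on *n_reps* independent draws.

    Per replicate: simulate a city (seed varied), apply the three-criterion
    linear-vs-spline rule, run the min-AIC threshold grid search, and (when
    ``B_bootstrap > 0``) the percentile-bootstrap CI. Aggregates bias, RMSE
    and CI coverage of the estimated threshold and the rate at which the
    non-linearity rule fires.
    """
    from .design import ModelSpec
    from .nonlinearity import compare_models
    from .threshold import DEFAULT_GRID, bootstrap_threshold_ci, grid_search_threshold

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spec = spec or ModelSpec()
    grid = DEFAULT_GRID if grid is None else grid
    t_true = cfg.exposure.t_star if cfg.exposure.kind == "hockey" else None

    t_hat = np.full(n_reps, np.nan)
    ci_lo = np.full(n_reps, np.nan)
    ci_hi = np.full(n_reps, np.nan)
    meets = np.zeros(n_reps, dtype=bool)
    daic = np.full(n_reps, np.nan)
    for r in range(n_reps):
        s = simulate_city(cfg.replace(seed=(cfg.seed + 1009 * r) % (2**31)), 0)
        cmp_ = compare_models(s, spec)
        meets[r] = cmp_.meets_criteria
        daic[r] = cmp_.delta_aic
        if run_search:
            tf = grid_search_threshold(s, spec, grid=grid)
            t_hat[r] = tf.threshold
            if B_bootstrap > 0:
                bs = bootstrap_threshold_ci(
                    s, spec, tf.threshold, B=B_bootstrap,
                    seed=(cfg.seed + 7919 * r + 1) % (2**31),
                )
                ci_lo[r], ci_hi[r] = bs.ci_low, bs.ci_high

    ok = np.isfinite(t_hat)
    if t_true is not None and ok.any():
        bias = float(np.mean(t_hat[ok]) - t_true)
        rmse = float(np.sqrt(np.mean((t_hat[ok] - t_true) ** 2)))
        have_ci = np.isfinite(ci_lo)
        coverage = (
            float(np.mean((ci_lo[have_ci] <= t_true) & (t_true <= ci_hi[have_ci])))
            if have_ci.any() else float("nan")
        )
    else:
        bias = rmse = coverage = float("nan")
    return RecoveryReport(
        n_reps=n_reps, t_true=t_true, t_hat=t_hat, ci_low=ci_lo, ci_high=ci_hi,
        meets_criteria=meets, delta_aic=daic, bias=bias, rmse=rmse,
        coverage=coverage, criteria_rate=float(meets.mean()),
    )
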