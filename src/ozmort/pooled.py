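"""City-combined models: Poisson regression with a city random intercept.

Two modes share the same fixed-effect design (confounders as in the
city-specific models, one shared time spline, pooled exposure term):

* ``random_intercept`` — each city gets a Gaussian intercept
  u_c ~ N(0, sigma^2). The marginal likelihood is maximised with a
  Laplace approximation: for fixed sigma^2 the joint (beta, u) mode is
  found by penalised IRLS (ridge on the u block only), then
  log L_m = l(beta, u) - u'u / (2 sigma^2) - m/2 log sigma^2
  - 1/2 log det(C' W C + I / sigma^2), profiled over log sigma^2 by
  bounded scalar optimisation. With one intercept per city and
  thousands of observations per city, the Laplace error is negligible.
* ``fixed_city`` — ordinary Poisson with city dummy variables; exact
  likelihood, used for deviance tests and as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import gammaln

from .data_io import moving_average
from .design import ModelSpec, natural_cubic_spline_basis
from .nonlinearity import ComparisonResult, CurveFit, classify_shape
from .glm import irls

log = logging.getLogger(__name__)


@dataclass
class PooledFit:
    """One pooled fit (either mode)."""

    mode: str                      # random_intercept | fixed_city
    params: np.ndarray             # fixed effects
    bse: np.ndarray
    cov: np.ndarray
    columns: list[str]
    city_ids: list[str]
    city_effects: np.ndarray       # predicted/estimated per-city intercepts
    random_variance: float         # sigma^2 (0 in fixed_city mode)
    llf: float                     # marginal (Laplace) or exact log-likelihood
    deviance: float
    k: int
    aic: float
    n: int
    converged: bool
    exposure_values: np.ndarray
    exposure_df: int

    def coef(self, name: str) -> float:
        return float(self.params[self.columns.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.columns.index(name)])


def _pooled_design(all_series, spec: ModelSpec):
    """Stack city designs on a shared covariate construction.

    Lag moving averages are computed per city (no leakage across city
    boundaries); spline bases and indicator coding are built once on the
    pooled rows so every city shares the same smooth terms.
    """
    if len(all_series) < 2:
        raise ValueError("pooled model needs >= 2 cities; use the city-specific path")
    frames = []
    for s in sorted(all_series, key=lambda s: s.city_id):
        df = pd.DataFrame(index=s.dates)
        df["city"] = s.city_id
        df["y"] = s.data[
            {"all": "deaths_all", "cvd": "deaths_cvd", "resp": "deaths_resp"}[spec.outcome]
        ].values
        df["expo"] = moving_average(s.data[spec.exposure].values, spec.o3_lag)
        df["temp"] = moving_average(s.data["temp"].values, spec.temp_lag)
        df["rh"] = s.data["rh"].values
        df["pm10"] = s.data["pm10"].values
        df["holiday"] = s.data["holiday"].values
        df["offset"] = np.log(s.daily_population().values)
        frames.append(df)
    pooled = pd.concat(frames)
    req = ["y", "expo", "temp", "rh", "offset"] + (["pm10"] if spec.include_pm10 else [])
    pooled = pooled.dropna(subset=req)

    dates = pd.DatetimeIndex(pooled.index)
    n = len(pooled)
    cols, names = [np.ones((n, 1))], ["intercept"]

    expo = pooled["expo"].values
    if spec.exposure_form == "linear":
        cols.append(expo[:, None]); names.append("o3")
        expo_df = 1
    else:
        B = natural_cubic_spline_basis(expo, spec.df_o3)
        cols.append(B); names.extend(f"o3_ns{i+1}" for i in range(B.shape[1]))
        expo_df = spec.df_o3
    expo_slice = slice(1, 1 + cols[-1].shape[1])

    tb = natural_cubic_spline_basis(pooled["temp"].values, spec.df_temp)
    cols.append(tb); names.extend(f"temp_ns{i+1}" for i in range(tb.shape[1]))
    rb = natural_cubic_spline_basis(pooled["rh"].values, spec.df_rh)
    cols.append(rb); names.extend(f"rh_ns{i+1}" for i in range(rb.shape[1]))
    if spec.include_pm10:
        cols.append(pooled["pm10"].values[:, None]); names.append("pm10")

    span_days = (dates.max() - dates.min()).days + 1
    time_df = max(1, round(spec.time_df_per_year * span_days / 365.25))
    tnum = (dates - dates.min()).days.values.astype(float)
    ts = natural_cubic_spline_basis(tnum, time_df)
    cols.append(ts); names.extend(f"time_ns{i+1}" for i in range(ts.shape[1]))

    warm = np.asarray((dates.month >= 4) & (dates.month <= 9), dtype=float)
    cols.append(warm[:, None]); names.append("warm")
    years = np.sort(np.unique(dates.year))
    if len(years) > 1:
        cols.append(np.column_stack([(dates.year == y).astype(float) for y in years[1:]]))
        names.extend(f"year_{y}" for y in years[1:])
    dow = dates.dayofweek
    cols.append(np.column_stack([(dow == d).astype(float) for d in range(1, 7)]))
    names.extend(f"dow_{d}" for d in range(1, 7))
    cols.append(pooled["holiday"].values[:, None]); names.append("holiday")

    X = np.column_stack(cols)
    city_ids = sorted(pooled["city"].unique())
    C = np.column_stack([(pooled["city"] == c).values.astype(float) for c in city_ids])
    return (X, names, pooled["y"].values.astype(float), pooled["offset"].values,
            C, city_ids, expo, expo_slice, expo_df)


def _penalized_irls(X, C, y, offset, lam, start=None, tol=1e-9, maxit=100):
    """Joint (beta, u) mode of the penalised Poisson log-likelihood.

    Ridge penalty lam = 1/sigma^2 applies to the u block only.
    """
    n, p = X.shape
    m = C.shape[1]
    Z = np.hstack([X, C])
    pen = np.zeros(p + m)
    pen[p:] = lam
    theta = np.zeros(p + m) if start is None else np.array(start, dtype=float)
    if start is None:
        theta[0] = np.log(max(y.mean(), 1e-10)) - offset.mean()
    eta = np.clip(Z @ theta + offset, -60, 60)
    mu = np.exp(eta)
    obj = float(np.sum(y * eta - mu)) - 0.5 * float(pen @ theta**2)
    H = None
    for it in range(maxit):
        w = mu
        z_work = (eta - offset) + (y - mu) / mu
        Zw = Z * w[:, None]
        H = Z.T @ Zw
        H[np.diag_indices_from(H)] += pen
        rhs = Zw.T @ z_work
        try:
            cf = linalg.cho_factor(H, check_finite=False)
            theta_new = linalg.cho_solve(cf, rhs, check_finite=False)
        except linalg.LinAlgError:
            return theta, None, False
        eta = np.clip(Z @ theta_new + offset, -500, 500)
        mu = np.exp(eta)
        obj_new = float(np.sum(y * eta - mu)) - 0.5 * float(pen @ theta_new**2)
        halve = 0
        while (not np.isfinite(obj_new) or obj_new < obj - 1e-8) and halve < 10:
            theta_new = (theta_new + theta) / 2
            eta = np.clip(Z @ theta_new + offset, -500, 500)
            mu = np.exp(eta)
            obj_new = float(np.sum(y * eta - mu)) - 0.5 * float(pen @ theta_new**2)
            halve += 1
        conv = abs(obj_new - obj) < tol * (abs(obj_new) + 0.1)
        theta, obj = theta_new, obj_new
        if conv:
            return theta, H, True
    return theta, H, False


def fit_pooled(all_series, spec: ModelSpec, mode: str = "random_intercept") -> PooledFit:
    """Fit the city-combined Poisson model."""
    if mode not in ("random_intercept", "fixed_city"):
        raise ValueError(f"unknown mode {mode!r}")
    X, names, y, offset, C, city_ids, expo, expo_slice, expo_df = _pooled_design(
        all_series, spec
    )
    n, p = X.shape
    m = C.shape[1]
    const = float(np.sum(gammaln(y + 1.0)))

    if mode == "fixed_city":
        # city dummies, first city as reference
        Xf = np.hstack([X, C[:, 1:]])
        namesf = names + [f"city_{c}" for c in city_ids[1:]]
        beta, XtWX, dev, conv, _, note = irls(Xf, y, offset)
        cov = linalg.inv(XtWX) if XtWX is not None else np.full((Xf.shape[1],) * 2, np.nan)
        eta = Xf @ beta + offset
        llf = float(np.sum(y * eta - np.exp(eta))) - const
        k = Xf.shape[1]
        effects = np.concatenate([[0.0], beta[p:]])
        return PooledFit(
            mode=mode, params=beta[:p], bse=np.sqrt(np.clip(np.diag(cov)[:p], 0, None)),
            cov=cov[:p, :p], columns=names, city_ids=city_ids,
            city_effects=effects, random_variance=0.0,
            llf=llf, deviance=dev, k=k, aic=2 * k - 2 * llf, n=n,
            converged=conv, exposure_values=expo, exposure_df=expo_df,
        )

    # --- Laplace-approximate random intercept --------------------------
    state = {"theta": None}

    def neg_marginal(log_s2):
        s2 = np.exp(log_s2)
        theta, H, conv = _penalized_irls(X, C, y, offset, 1.0 / s2, start=state["theta"])
        if H is None or not conv:
            return 1e12
        state["theta"] = theta.copy()
        u = theta[p:]
        eta = np.clip(np.hstack([X, C]) @ theta + offset, -500, 500)
        ll = float(np.sum(y * eta - np.exp(eta))) - const
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e12
        lm = ll - float(u @ u) / (2 * s2) - 0.5 * m * np.log(s2) - 0.5 * logdet
        return -lm

    res = optimize.minimize_scalar(
        neg_marginal, bounds=(np.log(1e-8), np.log(4.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    s2 = float(np.exp(res.x))
    theta, H, conv = _penalized_irls(X, C, y, offset, 1.0 / s2, start=state["theta"])
    llf = -float(res.fun)
    u = theta[p:]
    eta = np.clip(np.hstack([X, C]) @ theta + offset, -500, 500)
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * float(np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)))
    cov_all = linalg.inv(H)
    k = p + 1  # fixed effects + variance component
    return PooledFit(
        mode=mode, params=theta[:p], bse=np.sqrt(np.clip(np.diag(cov_all)[:p], 0, None)),
        cov=cov_all[:p, :p], columns=names, city_ids=city_ids,
        city_effects=u, random_variance=s2,
        llf=llf, deviance=dev, k=k, aic=2 * k - 2 * llf, n=n,
        converged=bool(conv and res.success), exposure_values=expo, exposure_df=expo_df,
    )


def pooled_curve(fit: PooledFit, reference_q: float = 0.05) -> CurveFit:
    """Concentration-response curve of a pooled exposure fit.

    A linear exposure fit yields a straight-line curve (slope x distance
    from the reference); a spline fit yields the full smooth curve.
    """
    expo = fit.exposure_values
    if "o3" in fit.columns:  # linear exposure term
        grid = np.arange(np.floor(expo.min()), np.ceil(expo.max()) + 0.5)
        ref = float(np.quantile(expo, reference_q))
        beta, se_b = fit.coef("o3"), fit.se("o3")
        p10, p90 = np.quantile(expo, [0.10, 0.90])
        return CurveFit(fit=None, grid=grid, log_rr=beta * (grid - ref),
                        se=np.abs(grid - ref) * se_b, reference=ref,
                        exposure_percentiles=(float(p10), float(p90)))
    probs = np.linspace(0, 1, fit.exposure_df + 1)
    knots = np.unique(np.quantile(np.unique(expo[np.isfinite(expo)]), probs))
    grid = np.arange(np.floor(expo.min()), np.ceil(expo.max()) + 0.5)
    ref = float(np.quantile(expo, reference_q))
    Bg = natural_cubic_spline_basis(grid, fit.exposure_df, knots=knots)
    Br = natural_cubic_spline_basis(np.array([ref]), fit.exposure_df, knots=knots)
    idx = [i for i, c in enumerate(fit.columns) if c.startswith("o3_ns")]
    beta = fit.params[idx]
    cov = fit.cov[np.ix_(idx, idx)]
    contrast = Bg - Br
    log_rr = contrast @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", contrast, cov, contrast), 0, None))
    p10, p90 = np.quantile(expo, [0.10, 0.90])
    return CurveFit(fit=None, grid=grid, log_rr=log_rr, se=se, reference=ref,
                    exposure_percentiles=(float(p10), float(p90)))


def compare_pooled(lin: PooledFit, spl: PooledFit) -> ComparisonResult:
    """dAIC and shape for the pooled linear vs spline exposure models.

    The deviance-difference p-value is exact only in fixed_city mode; under
    the Laplace approximation it is reported as NaN (not applicable).
    """
    if lin.mode != spl.mode:
        raise ValueError("pooled comparison requires the same mode")
    if lin.n != spl.n:
        raise ValueError("pooled comparison requires identical rows")
    delta_aic = spl.aic - lin.aic
    dev_diff = lin.deviance - spl.deviance
    df = spl.k - lin.k
    if lin.mode == "fixed_city" and df > 0:
        p = float(stats.chi2.sf(max(dev_diff, 0.0), df))
    else:
        p = float("nan")
    curve = pooled_curve(spl)
    shape = classify_shape(curve)
    beta = lin.coef("o3")
    se = lin.se("o3")
    return ComparisonResult(
        city_id="(pooled)",
        beta_linear=beta, se_linear=se,
        p_linear=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan"),
        aic_linear=lin.aic, aic_spline=spl.aic,
        delta_aic=delta_aic, deviance_diff=dev_diff, df=df, p_value=p,
        shape=shape,
        meets_criteria=bool(delta_aic < 0 and shape == "J_or_U"
                            and (np.isnan(p) or p < 0.05)),
        curve=curve,
    )
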