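"""Linear-vs-spline comparison and the three-criterion non-linearity rule.

A city is flagged as having a non-linear concentration-response
relationship (with a possible threshold) when, comparing a 3-df natural
spline ozone term against a linear one on identical rows:

1. dAIC = AIC(spline) - AIC(linear) is negative,
2. the deviance difference is significant (p < 0.05), and
3. the fitted curve is J- or U-shaped (declines or stays flat at low
   concentrations, rises at high ones, with an interior minimum).

The shape rule is operationalised numerically: the central-difference
derivative of the log relative rate must be <= 0 at the 10th percentile
of exposure, > 0 at the 90th, and the curve minimum must lie strictly
inside the evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ModelSpec, build_design, natural_cubic_spline_basis
from .glm import FitResult, fit_poisson
from .series import CitySeries

#: derivative magnitudes below this (per ppb) are treated as flat/borderline
FLAT_DERIVATIVE = 1e-5


@dataclass
class CurveFit:
    """Spline exposure fit plus its concentration-response curve.

    ``log_rr`` is the log relative rate versus the reference concentration
    (5th percentile of observed exposure), evaluated on a 1-ppb grid over
    the observed exposure range, with pointwise standard errors.
    """

    fit: FitResult
    grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference: float
    exposure_percentiles: tuple  # (10th, 90th) of observed exposure
    borderline: bool = False


@dataclass
class ComparisonResult:
    """Outcome of the three-criterion comparison for one city."""

    city_id: str
    beta_linear: float
    se_linear: float
    p_linear: float
    aic_linear: float
    aic_spline: float
    delta_aic: float
    deviance_diff: float
    df: int
    p_value: float
    shape: str                 # J_or_U | monotone | other
    meets_criteria: bool
    curve: CurveFit | None = None

    def as_row(self) -> dict:
        return {
            "city": self.city_id,
            "beta": self.beta_linear,
            "se": self.se_linear,
            "p_beta": self.p_linear,
            "aic_linear": self.aic_linear,
            "aic_spline": self.aic_spline,
            "delta_aic": self.delta_aic,
            "p_deviance": self.p_value,
            "shape": self.shape,
            "meets_criteria": self.meets_criteria,
        }


def fit_linear_model(s: CitySeries, spec: ModelSpec) -> FitResult:
    """Poisson fit with a single per-ppb exposure coefficient."""
    return fit_poisson(build_design(s, spec.replace(exposure_form="linear")))


def curve_from_fit(fit: FitResult, exposure_values: np.ndarray, df: int,
                   reference_q: float = 0.05) -> CurveFit:
    """Concentration-response curve implied by a spline exposure fit."""
    expo = exposure_values
    lo, hi = float(np.floor(expo.min())), float(np.ceil(expo.max()))
    grid = np.arange(lo, hi + 0.5, 1.0)
    ref = float(np.quantile(expo, reference_q))

    # basis must be rebuilt with the knots used at fit time: same quantile
    # rule on the same exposure values
    probs = np.linspace(0, 1, df + 1)
    knots = np.unique(np.quantile(np.unique(expo[np.isfinite(expo)]), probs))
    B_grid = natural_cubic_spline_basis(grid, df, knots=knots)
    B_ref = natural_cubic_spline_basis(np.array([ref]), df, knots=knots)

    idx = [i for i, c in enumerate(fit.columns) if c.startswith("o3_ns")]
    beta = fit.params[idx]
    cov = fit.cov[np.ix_(idx, idx)]
    contrast = B_grid - B_ref  # log-RR vs reference
    log_rr = contrast @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", contrast, cov, contrast), 0, None))
    p10, p90 = np.quantile(expo, [0.10, 0.90])
    return CurveFit(fit=fit, grid=grid, log_rr=log_rr, se=se, reference=ref,
                    exposure_percentiles=(float(p10), float(p90)))


def fit_spline_model(s: CitySeries, spec: ModelSpec) -> CurveFit:
    """Poisson fit with a natural-spline exposure term plus its curve."""
    dm = build_design(s, spec.replace(exposure_form="spline"))
    fit = fit_poisson(dm)
    return curve_from_fit(fit, dm.exposure_values, spec.df_o3)


def classify_shape(curve: CurveFit) -> str:
    """Label the concentration-response curve J_or_U, monotone, or other."""
    g, y = curve.grid, curve.log_rr
    if g[-1] - g[0] < 20:
        raise ValueError("grid must span at least 20 ppb to classify shape")
    if np.max(np.abs(y)) < 1e-10:
        return "other"  # degenerate flat curve
    deriv = np.gradient(y, g)  # central differences, one-sided at the ends
    p10, p90 = curve.exposure_percentiles
    d_lo = float(np.interp(p10, g, deriv))
    d_hi = float(np.interp(p90, g, deriv))
    curve.borderline = max(abs(d_lo), abs(d_hi)) < FLAT_DERIVATIVE
    i_min = int(np.argmin(y))
    interior_min = 0 < i_min < len(g) - 1
    if d_lo <= 0 and d_hi > 0 and interior_min:
        return "J_or_U"
    if np.all(deriv >= 0) or np.all(deriv <= 0):
        return "monotone"
    return "other"


def compare_models(s: CitySeries, spec: ModelSpec,
                   alpha: float = 0.05) -> ComparisonResult:
    """Fit linear and spline exposure models on identical rows and compare.

    Both models share every non-exposure column bit-identically (the
    exposure block is swapped on one design), so dAIC and the deviance
    difference isolate the exposure form.
    """
    dm_lin = build_design(s, spec.replace(exposure_form="linear"))
    spline_cols = natural_cubic_spline_basis(dm_lin.exposure_values, spec.df_o3)
    dm_spl = dm_lin.with_exposure_block(
        spline_cols, [f"o3_ns{i + 1}" for i in range(spline_cols.shape[1])]
    )
    fit_lin = fit_poisson(dm_lin)
    fit_spl = fit_poisson(dm_spl)
    if fit_lin.n != fit_spl.n:
        raise ValueError("linear and spline fits ended on different rows")
    if not (fit_lin.converged and fit_spl.converged):
        raise RuntimeError(
            f"{s.city_id}: fit did not converge "
            f"(linear: {fit_lin.diagnostic or 'ok'}; spline: {fit_spl.diagnostic or 'ok'})"
        )

    delta_aic = fit_spl.aic - fit_lin.aic
    dev_diff = fit_lin.deviance - fit_spl.deviance
    df = fit_spl.k - fit_lin.k
    p = float(stats.chi2.sf(max(dev_diff, 0.0), df)) if df > 0 else 1.0

    curve = curve_from_fit(fit_spl, dm_spl.exposure_values, spec.df_o3)
    shape = classify_shape(curve)
    beta = fit_lin.coef("o3")
    se = fit_lin.se("o3")
    p_lin = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return ComparisonResult(
        city_id=s.city_id,
        beta_linear=beta, se_linear=se, p_linear=p_lin,
        aic_linear=fit_lin.aic, aic_spline=fit_spl.aic,
        delta_aic=delta_aic, deviance_diff=dev_diff, df=df, p_value=p,
        shape=shape,
        meets_criteria=bool(delta_aic < 0 and p < alpha and shape == "J_or_U"),
        curve=curve,
    )


def select_lag(s: CitySeries, spec: ModelSpec, candidates):
    """Pick the exposure lag set with the most negative dAIC.

    Ties break to the lexicographically smaller lag set. Returns
    (chosen lag set, {lag set -> dAIC}).
    """
    candidates = [tuple(sorted(c)) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate lag set")
    table = {}
    for lags in candidates:
        table[lags] = compare_models(s, spec.replace(o3_lag=lags)).delta_aic
    best = min(sorted(table), key=lambda l: (table[l], l))
    return best, table


def modal_lag(per_city_choices):
    """Across cities, the lag set chosen most often (ties -> smaller set)."""
    from collections import Counter
    counts = Counter(tuple(c) for c in per_city_choices)
    top = max(counts.values())
    return min(l for l, c in counts.items() if c == top)
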