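"""Piecewise-linear threshold models, min-AIC grid search, bootstrap CI.

The exposure enters as two hinge terms, min(x, t) and max(x - t, 0), so
the fit yields distinct per-ppb slopes below and above the candidate
threshold t. One Poisson model is fitted per integer t over 10-60 ppb
on identical rows; the t with the smallest AIC is the threshold. Its
95% CI comes from a percentile bootstrap: day-rows are resampled with
replacement, the grid search is re-run inside t0 +/- 10 ppb, and the
2.5th/97.5th percentiles of the re-selected thresholds are reported.
Cycles in which no grid fit converges are excluded, as are individual
non-convergent grid points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import ModelSpec, build_design
from .glm import irls, fit_poisson, FitResult
from .series import CitySeries

log = logging.getLogger(__name__)

DEFAULT_GRID = np.arange(10, 61)  # 10..60 ppb, 1-ppb steps


def piecewise_terms(o3, t: float):
    """Hinge decomposition: below = min(o3, t), above = max(o3 - t, 0).

    The two terms always sum back to the concentration itself.
    """
    o3 = np.asarray(o3, dtype=float)
    below = np.minimum(o3, t)
    above = np.maximum(o3 - t, 0.0)
    return below, above


@dataclass
class ThresholdFit:
    """Selected threshold with its AIC profile and slope estimates."""

    city_id: str
    threshold: float
    slope_below: float
    se_below: float
    slope_above: float
    se_above: float
    aic: float
    profile: dict            # {t -> AIC} over every converged grid point
    failed_points: list = field(default_factory=list)
    fit: FitResult | None = None

    def excess_below(self):
        return excess_mortality_percent(self.slope_below, self.se_below)

    def excess_above(self):
        return excess_mortality_percent(self.slope_above, self.se_above)

    def as_row(self) -> dict:
        eb, eb_lo, eb_hi = self.excess_below()
        ea, ea_lo, ea_hi = self.excess_above()
        return {
            "city": self.city_id,
            "threshold": self.threshold,
            "excess_below_pct": eb, "excess_below_lo": eb_lo, "excess_below_hi": eb_hi,
            "excess_above_pct": ea, "excess_above_lo": ea_lo, "excess_above_hi": ea_hi,
        }


@dataclass
class BootstrapResult:
    """Percentile-bootstrap CI for a threshold."""

    city_id: str
    t0: float
    B: int
    n_converged: int
    draws: np.ndarray
    ci_low: float
    ci_high: float
    window: tuple
    seed: int
    warning: str = ""


def excess_mortality_percent(beta: float, se: float | None = None):
    """Percent change in daily mortality per 1 ppb, 100*(exp(beta) - 1).

    With *se*, also returns the 95% CI endpoints transformed from
    beta +/- 1.96 se.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    pct = 100.0 * (np.exp(beta) - 1.0)
    if se is None:
        return pct
    lo = 100.0 * (np.exp(beta - 1.96 * se) - 1.0)
    hi = 100.0 * (np.exp(beta + 1.96 * se) - 1.0)
    return pct, lo, hi


# ----------------------------------------------------------------------
class _GridEngine:
    """Shared machinery: one confounder block, hinge columns swapped per t.

    The design matrix is built once; for each candidate t only the two
    exposure columns are overwritten in place and the IRLS fit is
    warm-started from the neighbouring grid point's solution.
    """

    def __init__(self, s: CitySeries, spec: ModelSpec):
        # build at a mid-range t so neither hinge column is degenerate
        base = build_design(s, spec.replace(exposure_form="threshold",
                                            threshold=float(np.median(DEFAULT_GRID))))
        self.city_id = s.city_id
        self.columns = base.columns
        self.blocks = base.blocks
        self.X = np.ascontiguousarray(base.X)
        self.y = base.y
        self.offset = base.offset
        self.expo = base.exposure_values
        ib, ia = base.blocks["exposure"]
        self.i_below, self.i_above = int(ib), int(ia)

    def profile(self, grid, X=None, y=None, offset=None, expo=None,
                warm_starts=None):
        """AIC at every grid point; returns (aics, betas, failed).

        Fits are warm-started from the neighbouring grid point's solution
        (falling back to *warm_starts*, e.g. the original-data solutions,
        inside bootstrap cycles).
        """
        X = self.X if X is None else X
        y = self.y if y is None else y
        offset = self.offset if offset is None else offset
        expo = self.expo if expo is None else expo
        aics = np.full(len(grid), np.nan)
        betas = [None] * len(grid)
        failed = []
        k = X.shape[1]
        start = None
        for j, t in enumerate(grid):
            X[:, self.i_below] = np.minimum(expo, t)
            X[:, self.i_above] = np.maximum(expo - t, 0.0)
            if start is None and warm_starts is not None:
                start = warm_starts[j]
            beta, XtWX, dev, conv, _, note = irls(X, y, offset, start=start)
            if conv and XtWX is not None:
                eta = X @ beta + offset
                llf = float(y @ eta) - float(np.exp(eta).sum())  # + const, cancels in argmin
                aics[j] = 2.0 * k - 2.0 * llf
                betas[j] = beta.copy()
                start = beta
            else:
                failed.append((float(t), note))
                start = None
        return aics, betas, failed


def grid_search_threshold(s: CitySeries, spec: ModelSpec,
                          grid=DEFAULT_GRID) -> ThresholdFit:
    """Min-AIC threshold over the 1-ppb grid (smallest t on exact ties)."""
    grid = np.asarray(grid, dtype=float)
    eng = _GridEngine(s, spec)
    aics, betas, failed = eng.profile(grid)
    ok = np.isfinite(aics)
    if not ok.any():
        raise RuntimeError(f"{s.city_id}: every grid fit failed to converge")
    if len(failed) > 0.2 * len(grid):
        log.warning("%s: %d/%d grid fits failed to converge",
                    s.city_id, len(failed), len(grid))
    # argmin with smallest-t tie break: first index attaining the min
    j = int(np.flatnonzero(ok)[np.argmin(aics[ok])])
    t_hat = float(grid[j])

    # full fit at t_hat for SEs and the exact (constant-included) AIC
    dm = build_design(s, spec.replace(exposure_form="threshold", threshold=t_hat))
    fit = fit_poisson(dm, start=betas[j])
    # align the relative profile to the exact AIC scale at t_hat
    profile = {float(t): float(a - aics[j] + fit.aic)
               for t, a in zip(grid, aics) if np.isfinite(a)}
    return ThresholdFit(
        city_id=s.city_id, threshold=t_hat,
        slope_below=fit.coef("o3_below"), se_below=fit.se("o3_below"),
        slope_above=fit.coef("o3_above"), se_above=fit.se("o3_above"),
        aic=fit.aic, profile=profile,
        failed_points=failed, fit=fit,
    )


def bootstrap_threshold_ci(s: CitySeries, spec: ModelSpec, t0: float,
                           B: int = 5000, seed: int = 0,
                           window_halfwidth: float = 10.0,
                           grid_bounds=(10.0, 60.0)) -> BootstrapResult:
    """Percentile-bootstrap 95% CI for the threshold.

    Each cycle resamples analysis day-rows with replacement and re-runs the
    min-AIC search on the integer grid [t0 - 10, t0 + 10] intersected with
    the 10-60 ppb search range. Reproducible given *seed*.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    lo = max(grid_bounds[0], np.ceil(t0 - window_halfwidth))
    hi = min(grid_bounds[1], np.floor(t0 + window_halfwidth))
    grid = np.arange(lo, hi + 0.5)
    eng = _GridEngine(s, spec)
    rng = np.random.default_rng(int(seed) % (2**31))
    n = len(eng.y)
    # original-data solutions as warm starts for every cycle
    _, betas0, _ = eng.profile(grid)

    draws = np.full(B, np.nan)
    Xb = np.empty_like(eng.X)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        np.take(eng.X, idx, axis=0, out=Xb)
        yb = eng.y[idx]
        ob = eng.offset[idx]
        eb = eng.expo[idx]
        aics, _, _ = eng.profile(grid, X=Xb, y=yb, offset=ob, expo=eb,
                                 warm_starts=betas0)
        ok = np.isfinite(aics)
        if ok.any():
            j = int(np.flatnonzero(ok)[np.argmin(aics[ok])])
            draws[b] = grid[j]

    kept = draws[np.isfinite(draws)]
    n_conv = int(len(kept))
    warning = ""
    if n_conv == 0:
        raise RuntimeError(f"{s.city_id}: no bootstrap cycle converged")
    if n_conv < 0.5 * B:
        warning = f"only {n_conv}/{B} bootstrap cycles converged"
        log.warning("%s: %s", s.city_id, warning)
    ci_low, ci_high = np.percentile(kept, [2.5, 97.5])
    return BootstrapResult(
        city_id=s.city_id, t0=float(t0), B=B, n_converged=n_conv,
        draws=kept, ci_low=float(ci_low), ci_high=float(ci_high),
        window=(float(lo), float(hi)), seed=int(seed), warning=warning,
    )
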