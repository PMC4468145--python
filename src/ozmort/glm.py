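"""Poisson log-link regression by iteratively reweighted least squares.

The fitter is deliberately small and allocation-light: the threshold grid
search and bootstrap refit the same confounder block thousands of times
with only the two exposure columns changing, so warm starts and a raw
array interface dominate total runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln

#: relative deviance-change convergence tolerance
IRLS_TOL = 1e-9
IRLS_MAXIT = 100


class NotConvergedError(RuntimeError):
    pass


@dataclass
class FitResult:
    """One fitted Poisson model.

    ``llf`` is the full log-likelihood including the -ln(y!) terms, so AIC
    values are comparable across exposure forms fitted to the same rows;
    ``aic = 2k - 2 llf`` holds to machine precision.
    """

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    columns: list[str]
    llf: float
    deviance: float
    k: int
    aic: float
    n: int
    converged: bool
    n_iter: int
    diagnostic: str = ""
    mu: np.ndarray | None = field(default=None, repr=False)

    def coef_table(self) -> pd.DataFrame:
        z = np.divide(self.params, self.bse, out=np.full_like(self.params, np.nan),
                      where=self.bse > 0)
        return pd.DataFrame({
            "term": self.columns,
            "estimate": self.params,
            "se": self.bse,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        })

    def coef(self, name: str) -> float:
        return float(self.params[self.columns.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.columns.index(name)])


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


_dsyrk = linalg.get_blas_funcs("syrk", dtype=np.float64)
_dpotrf, _dpotrs = linalg.get_lapack_funcs(("potrf", "potrs"), dtype=np.float64)


def irls(X, y, offset, start=None, tol=IRLS_TOL, maxit=IRLS_MAXIT):
    """Raw IRLS solver. Returns (beta, XtWX, deviance, converged, n_iter, note).

    Convergence: relative change in deviance < *tol*; after *maxit*
    iterations the fit is flagged unconverged. Non-finite weights or a
    singular information matrix also flag non-convergence (never a silent
    answer).

    The deviance is tracked through the saturated log-likelihood
    (dev = 2(l_sat - l)), which avoids a per-iteration log; the
    information matrix is accumulated with a rank-k (syrk) update. Both
    matter: the threshold bootstrap calls this in the hundred-thousands.
    """
    n, k = X.shape
    # l_sat and l both omit the -ln(y!) constant; it cancels in the deviance
    ypos = y[y > 0]
    llsat = float(ypos @ np.log(ypos)) - float(y.sum())
    if start is None:
        beta = np.zeros(k)
        ybar = max(y.mean(), 1e-10)
        beta[0] = np.log(ybar) - offset.mean()  # column 0 is the intercept
    else:
        beta = np.array(start, dtype=float)

    eta = X @ beta + offset
    np.clip(eta, -60, 60, out=eta)  # guard wild warm starts
    mu = np.exp(eta)
    dev = 2.0 * (llsat - (float(y @ eta) - float(mu.sum())))
    XtWX = None
    for it in range(1, maxit + 1):
        w = mu  # Poisson log-link: working weight = mu
        if not np.all(np.isfinite(w)):
            return beta, None, dev, False, it, "non-finite weights"
        # X'WX via syrk on (sqrt(W)X)' (F-contiguous view, no copy);
        # X'Wz without materialising WX
        Xs = X * np.sqrt(w)[:, None]
        XtWX = _dsyrk(1.0, Xs.T, trans=0, lower=1)
        wz = w * (eta - offset) + (y - mu)
        XtWz = X.T @ wz
        c, info = _dpotrf(XtWX, lower=1, overwrite_a=False, clean=0)
        if info != 0:
            return beta, None, dev, False, it, "singular information matrix"
        beta_new, info = _dpotrs(c, XtWz, lower=1)
        if info != 0:
            return beta, None, dev, False, it, "singular information matrix"
        eta = X @ beta_new + offset
        if eta.max() > 500:
            return beta, None, dev, False, it, "divergent linear predictor"
        mu = np.exp(eta)
        dev_new = 2.0 * (llsat - (float(y @ eta) - float(mu.sum())))
        # step-halve if the deviance got worse (rare, separation-like data)
        halvings = 0
        while (not np.isfinite(dev_new) or dev_new > dev + 1e-8) and halvings < 10:
            beta_new = (beta_new + beta) / 2.0
            eta = X @ beta_new + offset
            mu = np.exp(eta)
            dev_new = 2.0 * (llsat - (float(y @ eta) - float(mu.sum())))
            halvings += 1
        beta = beta_new
        if abs(dev - dev_new) < tol * (abs(dev_new) + 0.1):
            return beta, XtWX, dev_new, True, it, ""
        dev = dev_new
    return beta, XtWX, dev, False, maxit, "max iterations reached"


def fit_poisson(design, start=None, tol=IRLS_TOL, maxit=IRLS_MAXIT) -> FitResult:
    """Fit the Poisson model described by a :class:`~ozmort.design.DesignMatrix`.

    Standard errors come from the inverse observed information (equal to the
    expected information under the canonical log link).
    """
    X, y, offset = design.X, design.y, design.offset
    beta, XtWX, dev, converged, it, note = irls(X, y, offset, start, tol, maxit)

    k = X.shape[1]
    if XtWX is not None and converged:
        XtWX = np.tril(XtWX) + np.tril(XtWX, -1).T  # syrk fills the lower triangle
        try:
            cov = linalg.inv(XtWX)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
            bse = np.full(k, np.nan)
            converged, note = False, "singular information at optimum"
    else:
        cov = np.full((k, k), np.nan)
        bse = np.full(k, np.nan)

    eta = np.clip(X @ beta + offset, -500, 500)
    mu = np.exp(eta)
    llf = float(np.sum(y * eta - mu - gammaln(y + 1.0)))
    aic = 2.0 * k - 2.0 * llf
    return FitResult(
        params=beta, bse=bse, cov=cov, columns=list(design.columns),
        llf=llf, deviance=dev, k=k, aic=aic, n=len(y),
        converged=converged, n_iter=it, diagnostic=note, mu=mu,
    )


def model_aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k - 2 ln L."""
    if not fit.converged:
        raise NotConvergedError(f"fit did not converge: {fit.diagnostic}")
    return 2.0 * fit.k - 2.0 * fit.llf


def deviance_test(nested: FitResult, full: FitResult) -> float:
    """Chi-square p-value for the deviance difference of nested fits.

    Both fits must be on identical rows; df is the (integer) difference in
    column counts, exact because all bases are unpenalised.
    """
    if nested.n != full.n:
        raise ValueError("deviance test requires fits on identical rows")
    if nested.k > full.k:
        raise ValueError("nested model has more parameters than the full model")
    df = full.k - nested.k
    stat = max(nested.deviance - full.deviance, 0.0)
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))
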