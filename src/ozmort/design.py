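"""Spline bases and regression design matrices.

The confounder model follows the standard time-series air-pollution
setup: smooth functions of temperature and humidity, a long-term time
trend spline (2 df per year by default), indicator blocks for warm
season, calendar year, day of week and holidays, a linear PM10 term and
a log-population offset. Exposure enters as a linear term, a natural
cubic spline, or a pair of piecewise (hinge) terms around a threshold.

All bases are unpenalised fixed-df regression splines, so the parameter
count k entering the AIC is the exact number of design columns and
nested-model deviance tests have integer degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.linalg

from .data_io import derive_calendar_covariates, moving_average
from .series import CitySeries

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The model spec asks for something the data cannot provide."""


# ----------------------------------------------------------------------
def natural_cubic_spline_basis(x, df: int, knots=None) -> np.ndarray:
    """Natural cubic spline basis with *df* columns (no intercept column).

    Interior knots sit at equally spaced quantiles of ``x``; boundary knots
    at the observed min/max. The fitted function is linear beyond the
    boundary knots (natural condition). ``df = 1`` degenerates to a single
    column affinely equivalent to ``x``.

    Uses the truncated-power natural basis: with knots xi_1 < ... < xi_K
    (K = df + 1), columns are ``x`` and ``d_k(x) - d_{K-1}(x)`` for
    k = 1..K-2 where ``d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k)``.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        xs = np.unique(x[np.isfinite(x)])
        if len(xs) < df + 1:
            raise ValueError(f"need at least {df + 1} distinct values for df={df}")
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(xs, probs)
        knots = np.unique(knots)
        if len(knots) < df + 1:
            raise ValueError("could not place distinct knots (too many ties)")
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    # scale for conditioning; affine maps leave the spline space unchanged
    lo, hi = knots[0], knots[-1]
    scale = hi - lo if hi > lo else 1.0
    z = (x - lo) / scale
    kn = (knots - lo) / scale

    cols = [z]
    if K > 2:
        def d(j):
            return (np.clip(z - kn[j], 0, None) ** 3 - np.clip(z - kn[-1], 0, None) ** 3) / (
                kn[-1] - kn[j]
            )

        d_last = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - d_last)
    return np.column_stack(cols)


# ----------------------------------------------------------------------
@dataclass
class ModelSpec:
    """Declarative description of one Poisson mortality model.

    Defaults mirror the primary analysis: lag0-1 mean ozone, same-day
    temperature, 3 df for the ozone spline, 2 df per year for the time
    trend, PM10 adjustment, and season/year/day-of-week/holiday
    indicators with a log-population offset.
    """

    outcome: str = "all"            # all | cvd | resp
    exposure: str = "o3_mean"       # o3_mean | o3_max1h
    exposure_form: str = "linear"   # linear | spline | threshold
    threshold: float | None = None  # ppb, for exposure_form == "threshold"
    o3_lag: tuple = (0, 1)
    temp_lag: tuple = (0,)
    df_o3: int = 3
    df_temp: int = 6
    df_rh: int = 3
    time_df_per_year: float = 2.0
    include_pm10: bool = True
    indicators: tuple = ("season", "year", "dow", "holiday")

    def __post_init__(self):
        if self.outcome not in ("all", "cvd", "resp"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in ("o3_mean", "o3_max1h"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.exposure_form not in ("linear", "spline", "threshold"):
            raise ValueError(f"unknown exposure_form {self.exposure_form!r}")
        if self.exposure_form == "threshold" and self.threshold is None:
            raise ValueError("threshold form needs a threshold value")
        for d in (self.df_o3, self.df_temp, self.df_rh):
            if d < 1:
                raise ValueError("all spline df must be >= 1")
        if self.time_df_per_year <= 0:
            raise ValueError("time_df_per_year must be > 0")
        if not self.o3_lag or not self.temp_lag:
            raise ValueError("lag sets must be non-empty")
        self.o3_lag = tuple(sorted(self.o3_lag))
        self.temp_lag = tuple(sorted(self.temp_lag))

    def replace(self, **kw) -> "ModelSpec":
        d = asdict(self)
        d.update(kw)
        return ModelSpec(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


OUTCOME_COLUMN = {"all": "deaths_all", "cvd": "deaths_cvd", "resp": "deaths_resp"}


@dataclass
class DesignMatrix:
    """Assembled regression problem for one Poisson fit.

    ``X`` has no missing entries and exactly one intercept column;
    ``blocks`` maps block name -> column indices, so the exposure block can
    be swapped without touching the confounder columns.
    """

    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray
    columns: list[str]
    blocks: dict[str, np.ndarray]
    dates: pd.DatetimeIndex
    exposure_values: np.ndarray  # lag-averaged exposure on the analysis rows
    dropped_aliased: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Labelled frame (date, y, offset, all predictor columns) for
        debugging; write with ``.to_csv()``."""
        df = pd.DataFrame(self.X, columns=self.columns, index=self.dates)
        df.insert(0, "y", self.y)
        df.insert(1, "offset", self.offset)
        return df

    def with_exposure_block(self, cols: np.ndarray, names: list[str]) -> "DesignMatrix":
        """Return a copy with the exposure block replaced by *cols*.

        Confounder columns are reused (bit-identical), enabling clean
        linear / spline / threshold comparisons on the same rows.
        """
        keep = np.setdiff1d(np.arange(self.k), self.blocks["exposure"])
        X = np.column_stack([self.X[:, keep], cols])
        columns = [self.columns[i] for i in keep] + list(names)
        blocks = {}
        remap = {old: new for new, old in enumerate(keep)}
        for name, idx in self.blocks.items():
            if name != "exposure":
                blocks[name] = np.array([remap[i] for i in idx], dtype=int)
        blocks["exposure"] = np.arange(len(keep), len(keep) + cols.shape[1])
        return DesignMatrix(
            y=self.y, X=X, offset=self.offset, columns=columns, blocks=blocks,
            dates=self.dates, exposure_values=self.exposure_values,
            dropped_aliased=list(self.dropped_aliased),
        )


def _exposure_block(expo: np.ndarray, spec: ModelSpec):
    """Columns and labels for the requested exposure form."""
    if spec.exposure_form == "linear":
        return expo[:, None], ["o3"]
    if spec.exposure_form == "spline":
        basis = natural_cubic_spline_basis(expo, spec.df_o3)
        return basis, [f"o3_ns{i + 1}" for i in range(basis.shape[1])]
    # threshold: hinge pair below/above
    t = float(spec.threshold)
    below = np.minimum(expo, t)
    above = np.maximum(expo - t, 0.0)
    return np.column_stack([below, above]), ["o3_below", "o3_above"]


def build_design(s: CitySeries, spec: ModelSpec, drop_aliased: bool = True) -> DesignMatrix:
    """Assemble the full design matrix implied by *spec* for one city.

    Rows are analysis days surviving lag trimming and complete-case
    filtering. Numerically collinear columns are detected by pivoted QR and
    dropped with a warning (the time spline and year indicators overlap by
    construction).
    """
    ycol = OUTCOME_COLUMN[spec.outcome]
    if not s.has_column(ycol):
        raise ConfigurationError(f"{s.city_id}: outcome column {ycol} unavailable")
    if not s.has_column(spec.exposure):
        raise ConfigurationError(f"{s.city_id}: exposure column {spec.exposure} unavailable")

    n_all = len(s)
    expo = moving_average(s.data[spec.exposure].values, spec.o3_lag)
    temp = moving_average(s.data["temp"].values, spec.temp_lag)
    rh = s.data["rh"].values.astype(float)
    pm10 = s.data["pm10"].values.astype(float)
    y = s.data[ycol].values.astype(float)
    offset = np.log(s.daily_population().values.astype(float))

    required = [y, expo, temp, rh, offset]
    if spec.include_pm10:
        required.append(pm10)
    mask = np.ones(n_all, dtype=bool)
    for arr in required:
        mask &= np.isfinite(arr)
    if mask.sum() <= 1:
        raise ValueError(f"{s.city_id}: no complete-case rows")

    dates = s.dates[mask]
    cal = derive_calendar_covariates(dates, s.data["holiday"].values[mask])
    y, expo, temp, rh, pm10, offset = (
        a[mask] for a in (y, expo, temp, rh, pm10, offset)
    )

    cols, names = [np.ones((mask.sum(), 1))], ["intercept"]
    blocks = {"intercept": np.array([0])}

    def add_block(name, mat, labels):
        start = sum(c.shape[1] for c in cols)
        cols.append(np.asarray(mat, dtype=float))
        names.extend(labels)
        blocks[name] = np.arange(start, start + mat.shape[1])

    exp_cols, exp_names = _exposure_block(expo, spec)
    add_block("exposure", exp_cols, exp_names)

    tb = natural_cubic_spline_basis(temp, spec.df_temp)
    add_block("temp", tb, [f"temp_ns{i + 1}" for i in range(tb.shape[1])])
    rb = natural_cubic_spline_basis(rh, spec.df_rh)
    add_block("rh", rb, [f"rh_ns{i + 1}" for i in range(rb.shape[1])])
    if spec.include_pm10:
        add_block("pm10", pm10[:, None], ["pm10"])

    n_years = len(dates) and (dates[-1] - dates[0]).days + 1
    time_df = max(1, round(spec.time_df_per_year * n_years / 365.25))
    tnum = (dates - dates[0]).days.values.astype(float)
    ts = natural_cubic_spline_basis(tnum, time_df)
    add_block("time", ts, [f"time_ns{i + 1}" for i in range(ts.shape[1])])

    if "season" in spec.indicators:
        add_block("season", cal["warm"].values[:, None].astype(float), ["warm"])
    if "year" in spec.indicators:
        years = np.sort(cal["year"].unique())
        if len(years) > 1:
            dummies = np.column_stack([(cal["year"].values == y_).astype(float) for y_ in years[1:]])
            add_block("year", dummies, [f"year_{y_}" for y_ in years[1:]])
    if "dow" in spec.indicators:
        dummies = np.column_stack([(cal["dow"].values == d).astype(float) for d in range(1, 7)])
        add_block("dow", dummies, [f"dow_{d}" for d in range(1, 7)])
    if "holiday" in spec.indicators:
        add_block("holiday", cal["holiday"].values[:, None].astype(float), ["holiday"])

    X = np.column_stack(cols)
    dm = DesignMatrix(
        y=y, X=X, offset=offset, columns=names, blocks=blocks, dates=dates,
        exposure_values=expo,
    )
    if drop_aliased:
        dm = _drop_aliased(dm, s.city_id)
    return dm


def _drop_aliased(dm: DesignMatrix, label: str = "") -> DesignMatrix:
    """Drop numerically collinear columns, found via pivoted QR."""
    X = dm.X
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = scipy.linalg.qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank == X.shape[1]:
        return dm
    drop = np.sort(piv[rank:])
    dropped_names = [dm.columns[i] for i in drop]
    log.warning("%s: dropping aliased column(s) %s", label, dropped_names)
    keep = np.setdiff1d(np.arange(X.shape[1]), drop)
    remap = {old: new for new, old in enumerate(keep)}
    blocks = {
        name: np.array([remap[i] for i in idx if i in remap], dtype=int)
        for name, idx in dm.blocks.items()
    }
    return DesignMatrix(
        y=dm.y, X=X[:, keep], offset=dm.offset,
        columns=[dm.columns[i] for i in keep], blocks=blocks, dates=dm.dates,
        exposure_values=dm.exposure_values,
        dropped_aliased=dm.dropped_aliased + dropped_names,
    )
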