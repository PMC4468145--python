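"""Reading, writing and summarising daily city series.

The on-disk format is a plain CSV with one row per (city, date). Column
names are mapped to the canonical schema through a ``schema`` dict so that
differently-labelled deposits can be ingested without editing code.
Missing values are empty cells or ``NA``; they are preserved as missing,
never imputed to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    COUNT_COLUMNS,
    DAILY_COLUMNS,
    CitySeries,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: columns that must be present in any input file
MANDATORY = ("city", "date", "deaths_all", "o3_mean", "pm10", "temp", "rh", "population")

#: conversion factor from suspended particulate matter to PM10 used by the
#: Japanese monitoring network
SPM_TO_PM10 = 1.16


def convert_spm_to_pm10(spm):
    """Convert suspended particulate matter (ug/m3) to PM10 (ug/m3).

    Japanese stations report SPM rather than PM10; the two scales are
    related by a fixed factor of 1.16.
    """
    arr = np.asarray(spm, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("SPM concentrations must be non-negative")
    out = arr * SPM_TO_PM10
    return float(out) if np.isscalar(spm) else out


def moving_average(values, lag_set) -> np.ndarray:
    """Moving average of *values* over the day-lags in *lag_set*.

    ``lag_set = {0, 1}`` gives the mean of same-day and previous-day values
    (the lag0-1 exposure metric). Days whose window extends before the start
    of the series are marked missing; within a valid window, missing members
    are dropped from the mean (all-missing windows stay missing).
    """
    lags = sorted(int(l) for l in lag_set)
    if not lags:
        raise ValueError("lag_set must be non-empty")
    if lags[0] < 0:
        raise ValueError("lags must be >= 0")
    x = np.asarray(values, dtype=float)
    n = len(x)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for l in lags:
        shifted = np.full(n, np.nan)
        shifted[l:] = x[: n - l] if l else x
        ok = np.isfinite(shifted)
        acc[ok] += shifted[ok]
        cnt[ok] += 1
    out = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    out[: max(lags)] = np.nan  # window precedes series start
    return out


def derive_calendar_covariates(dates: pd.DatetimeIndex, holidays=None) -> pd.DataFrame:
    """Per-day calendar indicator table.

    warm season is April through September; cold is October through March.
    """
    dates = pd.DatetimeIndex(dates)
    out = pd.DataFrame(index=dates)
    out["warm"] = ((dates.month >= 4) & (dates.month <= 9)).astype(int)
    out["year"] = dates.year
    out["dow"] = dates.dayofweek  # 0 = Monday
    out["holiday"] = (
        np.asarray(holidays, dtype=float) if holidays is not None else 0.0
    )
    return out


# ----------------------------------------------------------------------
@dataclass
class SummaryStats:
    """Per-city descriptive statistics (the Table-1-style summary)."""

    city_id: str
    n_days: int
    means: dict[str, float]
    sds: dict[str, float]
    mean_daily_deaths: float
    cutoff: float
    prop_o3_le_cutoff: float

    def as_row(self) -> dict:
        row = {"city": self.city_id, "n_days": self.n_days}
        for v in ("o3_mean", "pm10", "temp", "rh"):
            row[f"mean_{v}"] = self.means.get(v, np.nan)
            row[f"sd_{v}"] = self.sds.get(v, np.nan)
        row["mean_daily_deaths"] = self.mean_daily_deaths
        row[f"prop_o3_le_{self.cutoff:g}ppb"] = self.prop_o3_le_cutoff
        return row


def summarize_series(s: CitySeries, cutoff: float = 20.0) -> SummaryStats:
    """Means/SDs over non-missing days plus the share of low-ozone days.

    The proportion is #days with mean O3 <= *cutoff* (ppb) over non-missing
    O3 days; it is monotone non-decreasing in the cutoff.
    """
    means, sds = {}, {}
    for col in ("o3_mean", "o3_max1h", "pm10", "temp", "rh"):
        vals = s.data[col].dropna()
        if len(vals) == 0:
            log.warning("%s: variable %s all-missing", s.city_id, col)
            means[col], sds[col] = np.nan, np.nan
        else:
            means[col] = float(vals.mean())
            sds[col] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    o3 = s.data["o3_mean"].dropna()
    prop = float((o3 <= cutoff).mean()) if len(o3) else np.nan
    return SummaryStats(
        city_id=s.city_id,
        n_days=len(s),
        means=means,
        sds=sds,
        mean_daily_deaths=float(s.data["deaths_all"].mean()),
        cutoff=cutoff,
        prop_o3_le_cutoff=prop,
    )


# ----------------------------------------------------------------------
DEFAULT_SCHEMA = {name: name for name in ("city", "country", "date", "population") + DAILY_COLUMNS}


def read_daily_series(path, schema: dict | None = None, date_format: str | None = None,
                      pm_is_spm: bool = False):
    """Read a one-row-per-(city, date) CSV into a list of :class:`CitySeries`.

    Parameters
    ----------
    path
        CSV file path.
    schema
        Mapping canonical name -> column name in the file. Unmapped optional
        columns are filled with NaN. Dates are ISO 8601 unless *date_format*
        declares another dialect.
    pm_is_spm
        Declare that the particulate column holds SPM rather than PM10;
        values are converted on ingestion (x 1.16). Off by default: deposited
        multi-city files are normally already converted.

    Returns
    -------
    list of CitySeries, sorted by city_id. Calendar gaps inside a city's
    span are filled with missing rows and reported via logging.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    raw = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    for canon in MANDATORY:
        if colmap[canon] not in raw.columns:
            raise SchemaError(f"missing mandatory column {colmap[canon]!r} (for {canon})")

    df = pd.DataFrame()
    for canon, src in colmap.items():
        if src in raw.columns:
            df[canon] = raw[src]
    df["date"] = pd.to_datetime(df["date"], format=date_format)
    if pm_is_spm:
        df["pm10"] = convert_spm_to_pm10(df["pm10"].values)

    dup = df.duplicated(subset=["city", "date"])
    if dup.any():
        c, d = df.loc[dup.idxmax(), ["city", "date"]]
        raise ValidationError(f"duplicate (city, date) row: ({c}, {d.date()})")

    for col in COUNT_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            if len(vals) and not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"non-integer death count in column {col!r}")

    out = []
    for city, grp in df.groupby("city", sort=True):
        grp = grp.sort_values("date").set_index("date")
        full = pd.date_range(grp.index[0], grp.index[-1], freq="D")
        n_gaps = len(full) - len(grp)
        if n_gaps:
            log.warning("%s: %d missing calendar days filled as missing rows", city, n_gaps)
        grp = grp.reindex(full)
        country = ""
        if "country" in grp.columns and grp["country"].notna().any():
            country = str(grp["country"].dropna().iloc[0])
        pop = (
            grp["population"]
            .groupby(grp.index.year)
            .apply(lambda v: float(v.dropna().iloc[0]) if v.notna().any() else np.nan)
            .to_dict()
        )
        data = pd.DataFrame(index=grp.index)
        for col in DAILY_COLUMNS:
            data[col] = grp[col] if col in grp.columns else np.nan
        if data["holiday"].isna().all():
            data["holiday"] = 0.0
        out.append(CitySeries(city_id=str(city), country=country, data=data, population=pop))
    return out


def write_daily_series(series_list, path) -> None:
    """Write series back to the CSV layout :func:`read_daily_series` accepts."""
    frames = []
    for s in series_list:
        df = s.data.copy()
        df.insert(0, "city", s.city_id)
        df.insert(1, "country", s.country)
        df.insert(2, "date", df.index.strftime("%Y-%m-%d"))
        df["population"] = s.daily_population().values
        frames.append(df.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def summary_table(series_list, cutoff: float = 20.0) -> pd.DataFrame:
    """Table-1-style summary across cities, plus the pooled low-ozone share."""
    rows = [summarize_series(s, cutoff).as_row() for s in series_list]
    return pd.DataFrame(rows)


def pooled_proportion_below(series_list, cutoff: float = 20.0) -> float:
    """Share of all city-days (pooled) with mean O3 <= cutoff ppb."""
    vals = pd.concat([s.data["o3_mean"] for s in series_list]).dropna()
    return float((vals <= cutoff).mean())
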