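"""City-level daily time series container.

A :class:`CitySeries` holds one city's daily mortality counts, pollutant
concentrations, weather and population, on a strictly consecutive daily
calendar. It is the unit of analysis for the city-specific models and the
element pooled by the multi-city model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical per-day columns (besides the date index)
DAILY_COLUMNS = (
    "deaths_all",
    "deaths_cvd",
    "deaths_resp",
    "o3_mean",
    "o3_max1h",
    "pm10",
    "temp",
    "rh",
    "holiday",
)

COUNT_COLUMNS = ("deaths_all", "deaths_cvd", "deaths_resp")


class ValidationError(ValueError):
    """A series or input file violates a structural invariant."""


class SchemaError(ValueError):
    """An input file is missing a mandatory column."""


@dataclass
class CitySeries:
    """Daily exposure / weather / mortality series for one city.

    Parameters
    ----------
    city_id
        City label (e.g. ``"Seoul"``).
    country
        Country label; free text, may be empty.
    data
        Frame indexed by a consecutive ``DatetimeIndex`` (step one day) with
        the columns in :data:`DAILY_COLUMNS`. Optional columns
        (``o3_max1h``, ``deaths_cvd``, ``deaths_resp``) may be all-missing.
        Missing numeric values are NaN, never zero.
    population
        Yearly population of the city (persons, age >= 30), mapping
        calendar year -> persons. Must cover every year the series spans.
    """

    city_id: str
    country: str
    data: pd.DataFrame
    population: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError(f"{self.city_id}: index must be datetime")
        if len(idx) == 0:
            raise ValidationError(f"{self.city_id}: empty series")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"{self.city_id}: duplicate date {dup.date()}")
        steps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if len(steps) and not np.all(steps == 1):
            raise ValidationError(
                f"{self.city_id}: dates must be consecutive (step 1 day); "
                f"first bad step after {idx[int(np.argmax(steps != 1))].date()}"
            )
        for col in DAILY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"{self.city_id}: missing column {col!r}")
        for col in COUNT_COLUMNS:
            vals = self.data[col].dropna()
            if len(vals) and not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"{self.city_id}: non-integer counts in {col}")
            if (vals < 0).any():
                raise ValidationError(f"{self.city_id}: negative counts in {col}")
        o3 = self.data["o3_mean"].dropna()
        if (o3 < 0).any():
            raise ValidationError(f"{self.city_id}: negative o3_mean")
        rh = self.data["rh"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValidationError(f"{self.city_id}: rh outside [0, 100]")
        years = range(idx[0].year, idx[-1].year + 1)
        for y in years:
            pop = self.population.get(y)
            if pop is None or not pop > 0:
                raise ValidationError(
                    f"{self.city_id}: population missing or non-positive for {y}"
                )

    # ------------------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def daily_population(self) -> pd.Series:
        """Per-day population by broadcasting the yearly values."""
        years = self.data.index.year
        return pd.Series(
            [self.population[y] for y in years], index=self.data.index, name="population"
        )

    def has_column(self, col: str) -> bool:
        """True when *col* exists and has at least one observed value."""
        return col in self.data.columns and self.data[col].notna().any()
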