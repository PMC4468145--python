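import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ozmort import (
    CitySeries,
    ValidationError,
    convert_spm_to_pm10,
    derive_calendar_covariates,
    moving_average,
    read_daily_series,
    summarize_series,
    write_daily_series,
)
from ozmort.data_io import pooled_proportion_below
from ozmort.series import SchemaError
from ozmort.synthetic import SyntheticConfig, simulate_study


def _toy_frame(city, n=10, start="2000-01-01"):
    dates = pd.date_range(start, periods=n, freq="D")
    return pd.DataFrame({
        "city": city, "country": "KR",
        "date": dates.strftime("%Y-%m-%d"),
        "deaths_all": np.arange(n) + 5, "deaths_cvd": 2, "deaths_resp": 1,
        "o3_mean": 20.0 + np.arange(n), "o3_max1h": 30.0,
        "pm10": 50.0, "temp": 15.0, "rh": 60.0,
        "holiday": 0, "population": 1.0e6,
    })


class TestReadDailySeries:
    def test_two_city_roundtrip(self, tmp_path):
        df = pd.concat([_toy_frame("Seoul"), _toy_frame("Busan")])
        path = tmp_path / "toy.csv"
        df.to_csv(path, index=False)
        series = read_daily_series(path)
        assert [s.city_id for s in series] == ["Busan", "Seoul"]
        assert all(len(s) == 10 for s in series)

    def test_duplicate_city_date_rejected(self, tmp_path):
        df = _toy_frame("Seoul")
        df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="Seoul, 2000-01-01"):
            read_daily_series(path)

    def test_missing_mandatory_column_named(self, tmp_path):
        df = _toy_frame("Seoul").drop(columns=["o3_mean"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="o3_mean"):
            read_daily_series(path)

    def test_non_integer_death_count_rejected(self, tmp_path):
        df = _toy_frame("Seoul")
        df["deaths_all"] = df["deaths_all"].astype(float)
        df.loc[3, "deaths_all"] = 4.5
        path = tmp_path / "frac.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="deaths_all"):
            read_daily_series(path)

    def test_calendar_gap_filled_as_missing(self, tmp_path):
        df = _toy_frame("Seoul").drop(index=[4])
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        (s,) = read_daily_series(path)
        assert len(s) == 10  # reindexed onto consecutive days
        assert np.isnan(s.data["o3_mean"].iloc[4])

    def test_missing_cells_stay_missing(self, tmp_path):
        df = _toy_frame("Seoul")
        df.loc[2, "pm10"] = np.nan
        path = tmp_path / "na.csv"
        df.to_csv(path, index=False, na_rep="NA")
        (s,) = read_daily_series(path)
        assert np.isnan(s.data["pm10"].iloc[2])

    def test_spm_flag_converts_on_ingestion(self, tmp_path):
        df = _toy_frame("Seoul")
        path = tmp_path / "spm.csv"
        df.to_csv(path, index=False)
        (s,) = read_daily_series(path, pm_is_spm=True)
        assert s.data["pm10"].iloc[0] == pytest.approx(50.0 * 1.16)

    def test_schema_mapping(self, tmp_path):
        df = _toy_frame("Seoul").rename(columns={"o3_mean": "O3", "deaths_all": "nonacc"})
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        (s,) = read_daily_series(path, schema={"o3_mean": "O3", "deaths_all": "nonacc"})
        assert s.data["o3_mean"].iloc[0] == 20.0

    def test_write_read_roundtrip_synthetic(self, tmp_path):
        series = simulate_study(SyntheticConfig(n_cities=2, n_days=731, seed=3))
        path = tmp_path / "rt.csv"
        write_daily_series(series, path)
        back = read_daily_series(path)
        for orig, rt in zip(series, back):
            # counts bit-identical, reals to full precision
            assert np.array_equal(orig.data["deaths_all"].values, rt.data["deaths_all"].values)
            np.testing.assert_allclose(
                orig.data["o3_mean"].values, rt.data["o3_mean"].values, rtol=1e-12
            )
            assert orig.population == rt.population


class TestSpmConversion:
    @pytest.mark.parametrize("spm,expected", [(0.0, 0.0), (30.0, 34.8), (100.0, 116.0)])
    def test_factor(self, spm, expected):
        assert convert_spm_to_pm10(spm) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_spm_to_pm10(-1.0)


class TestMovingAverage:
    @pytest.mark.parametrize(
        "lags,expected",
        [
            ({0}, [10.0, 20.0, 30.0]),
            ({0, 1}, [np.nan, 15.0, 25.0]),
            ({0, 1, 2}, [np.nan, np.nan, 20.0]),
        ],
    )
    def test_small_windows(self, lags, expected):
        out = moving_average([10.0, 20.0, 30.0], lags)
        np.testing.assert_array_equal(out, expected)

    def test_empty_lag_set_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], set())

    def test_missing_member_dropped_from_mean(self):
        out = moving_average([10.0, np.nan, 30.0, 40.0], {0, 1})
        np.testing.assert_array_equal(out, [np.nan, 10.0, 30.0, 35.0])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_lag0_identity(self, xs):
        np.testing.assert_array_equal(moving_average(xs, {0}), np.asarray(xs))


class TestCalendar:
    def test_warm_cold_boundary(self):
        cal = derive_calendar_covariates(pd.DatetimeIndex(["2003-04-15", "2003-10-01"]))
        assert cal["warm"].tolist() == [1, 0]

    def test_dow_and_year(self):
        cal = derive_calendar_covariates(pd.DatetimeIndex(["2000-01-02"]))
        assert cal["dow"].iloc[0] == 6  # Sunday
        assert cal["year"].iloc[0] == 2000


class TestSummaries:
    def test_degenerate_constant_series(self):
        dates = pd.date_range("2001-01-01", periods=100, freq="D")
        data = pd.DataFrame({
            "deaths_all": 5.0, "deaths_cvd": 1.0, "deaths_resp": 1.0,
            "o3_mean": 20.0, "o3_max1h": np.nan, "pm10": 40.0,
            "temp": 10.0, "rh": 50.0, "holiday": 0.0,
        }, index=dates)
        s = CitySeries("X", "", data, {2001: 1e6})
        stats = summarize_series(s, cutoff=20.0)
        assert stats.means["o3_mean"] == 20.0
        assert stats.sds["o3_mean"] == 0.0
        assert stats.prop_o3_le_cutoff == 1.0
        assert np.isnan(stats.means["o3_max1h"])

    def test_proportion_monotone_in_cutoff(self, null_city):
        props = [summarize_series(null_city, c).prop_o3_le_cutoff for c in range(0, 60, 5)]
        assert all(b >= a for a, b in zip(props, props[1:]))
        assert props[-1] <= 1.0 and props[0] >= 0.0

    def test_pooled_proportion_between_city_extremes(self):
        series = simulate_study(SyntheticConfig(n_cities=3, n_days=731, seed=9))
        pooled = pooled_proportion_below(series, 20.0)
        per_city = [summarize_series(s, 20.0).prop_o3_le_cutoff for s in series]
        assert min(per_city) <= pooled <= max(per_city)
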