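import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vernaltherm as vt
from vernaltherm.climate_io import SnowDetectionParams, _detect_cadence
from vernaltherm.errors import (
    ContractError,
    EmptyInputError,
    FormatError,
    InsufficientDataError,
)

from conftest import make_constant_series


def write_csv(path, rows, header="timestamp,temp_c"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadTemperatureCsv:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [
            "2011-09-01T00:00:00,5.0",
            "2011-09-01T08:00:00,6.0",
            "2011-09-02T11:00:00,7.0",
        ])
        series = vt.read_temperature_csv(p)
        assert len(series) == 3
        assert series.cadence == "irregular"
        assert list(series.temps_c) == [5.0, 6.0, 7.0]

    def test_duplicate_timestamps_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [
            "2011-09-01T00:00:00,5.0",
            "2011-09-01T00:00:00,7.0",
            "2011-09-01T01:00:00,4.0",
        ])
        with pytest.warns(UserWarning, match="duplicated"):
            series = vt.read_temperature_csv(p)
        assert len(series) == 2
        assert series.temps_c[0] == pytest.approx(6.0)

    def test_hourly_cadence_detected_on_synthetic_trace(self, tmp_path, autumn_series):
        # 1 Aug - 30 Nov = 122 days -> 2928 hourly rows
        assert len(autumn_series) == 122 * 24
        p = tmp_path / "t.csv"
        vt.write_temperature_csv(autumn_series, p)
        series = vt.read_temperature_csv(p)
        assert series.cadence == "hourly"
        assert len(series) == 2928

    def test_unparseable_timestamp_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, ["2011-09-01T00:00:00,5.0", "not-a-date,6.0"])
        with pytest.raises(FormatError, match="row 2"):
            vt.read_temperature_csv(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            vt.read_temperature_csv(p)

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time,degrees\n2011-09-01,5.0\n")
        with pytest.raises(FormatError):
            vt.read_temperature_csv(p)

    def test_roundtrip_bit_identical(self, tmp_path, autumn_series):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        vt.write_temperature_csv(autumn_series, p1)
        vt.write_temperature_csv(vt.read_temperature_csv(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestSeriesValidation:
    def test_rejects_out_of_bounds(self):
        frame = pd.DataFrame(
            {"timestamp": pd.date_range("2011-01-01", periods=2, freq="h"),
             "temp_c": [5.0, 99.0]}
        )
        with pytest.raises(ContractError):
            vt.TemperatureSeries(frame=frame)

    def test_rejects_unsorted(self):
        frame = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2011-01-02", "2011-01-01"]), "temp_c": [1.0, 2.0]}
        )
        with pytest.raises(ContractError):
            vt.TemperatureSeries(frame=frame)

    def test_thrice_daily_cadence(self):
        ts = []
        for day in range(1, 4):
            for hour in (6, 12, 18):
                ts.append(pd.Timestamp(2011, 9, day, hour))
        assert _detect_cadence(pd.DatetimeIndex(ts)) == "thrice_daily"


class TestDailyMeans:
    def test_thrice_daily_mean(self):
        frame = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp(2011, 9, 1, h) for h in (6, 12, 18)],
                "temp_c": [2.0, 8.0, 5.0],
            }
        )
        series = vt.TemperatureSeries(frame=frame, cadence="thrice_daily")
        out = vt.daily_means(series, policy="thrice_daily")
        assert len(out) == 1
        assert out["daily_mean_c"].iloc[0] == pytest.approx(5.0)
        assert bool(out["complete"].iloc[0])

    def test_missing_evening_reading_incomplete(self):
        frame = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp(2011, 9, 1, h) for h in (6, 12)],
                "temp_c": [2.0, 8.0],
            }
        )
        series = vt.TemperatureSeries(frame=frame, cadence="thrice_daily")
        out = vt.daily_means(series, policy="thrice_daily")
        assert not bool(out["complete"].iloc[0])
        assert out["daily_mean_c"].iloc[0] == pytest.approx(5.0)

    def test_constant_hourly_day(self):
        series = make_constant_series(8.0, days=1)
        out = vt.daily_means(series, policy="hourly")
        assert out["daily_mean_c"].iloc[0] == pytest.approx(8.0)
        assert bool(out["complete"].iloc[0])

    def test_constant_series_exact_for_every_complete_day(self):
        series = make_constant_series(3.25, days=10)
        out = vt.daily_means(series)
        assert (out.loc[out["complete"], "daily_mean_c"] == 3.25).all()

    def test_short_gap_interpolated_long_gap_incomplete(self):
        ts = pd.date_range("2011-09-01", periods=72, freq="h")
        keep = np.ones(72, dtype=bool)
        keep[30:33] = False   # 3 h gap on day 2 -> interpolated, still complete
        keep[52:62] = False   # 10 h gap on day 3 -> incomplete
        frame = pd.DataFrame({"timestamp": ts[keep], "temp_c": 5.0})
        series = vt.TemperatureSeries(frame=frame, cadence="hourly")
        out = vt.daily_means(series, policy="hourly")
        assert bool(out["complete"].iloc[1])
        assert not bool(out["complete"].iloc[2])

    def test_empty_series_rejected(self):
        frame = pd.DataFrame({"timestamp": pd.to_datetime([]), "temp_c": []})
        series = vt.TemperatureSeries(frame=frame)
        with pytest.raises(EmptyInputError):
            vt.daily_means(series)


def dailies_from_values(values, start="2011-08-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame(
        {"date": dates, "daily_mean_c": values, "n_readings": 3, "complete": True}
    )


class TestAutumnSummary:
    WINDOW = vt.VernalizationWindow(0.0, 15.0, basis="daily_mean")

    def test_synthetic_season_mean_recovered(self):
        cfg = vt.WeatherConfig(mean_start_c=8.86, mean_end_c=8.86, noise_sd_c=2.5, seed=1)
        dailies = vt.daily_means(vt.generate_weather(cfg))
        summary = vt.autumn_summary(dailies, vt.SeasonWindow(), self.WINDOW)
        assert summary.mean_of_daily_means_c == pytest.approx(8.86, abs=0.5)
        assert summary.n_days == 122

    def test_all_outside_window(self):
        summary = vt.autumn_summary(dailies_from_values([20.0] * 10), vt.SeasonWindow(), self.WINDOW)
        assert summary.fraction_days_in_window == 0.0

    def test_strict_membership(self):
        summary = vt.autumn_summary(
            dailies_from_values([-1.0, 5.0, 14.0, 16.0]), vt.SeasonWindow(), self.WINDOW
        )
        assert summary.fraction_days_in_window == pytest.approx(0.5)

    def test_bound_values_excluded(self):
        summary = vt.autumn_summary(
            dailies_from_values([0.0, 15.0, 7.0]), vt.SeasonWindow(), self.WINDOW
        )
        assert summary.fraction_days_in_window == pytest.approx(1 / 3)

    def test_incomplete_days_excluded(self):
        dailies = dailies_from_values([5.0, 5.0, 50.0])
        dailies.loc[2, "complete"] = False
        dailies.loc[2, "daily_mean_c"] = 20.0
        summary = vt.autumn_summary(dailies, vt.SeasonWindow(), self.WINDOW)
        assert summary.n_days == 2
        assert summary.fraction_days_in_window == 1.0

    def test_no_complete_days_raises(self):
        dailies = dailies_from_values([5.0])
        dailies["complete"] = False
        with pytest.raises(InsufficientDataError):
            vt.autumn_summary(dailies, vt.SeasonWindow(), self.WINDOW)

    def test_multi_year_sd_over_yearly_means(self):
        d1 = dailies_from_values([8.0] * 122, start="2011-08-01")
        d2 = dailies_from_values([10.0] * 122, start="2012-08-01")
        summary = vt.autumn_summary(pd.concat([d1, d2]), vt.SeasonWindow(), self.WINDOW)
        assert summary.mean_of_daily_means_c == pytest.approx(9.0)
        assert summary.sd_of_daily_means_c == pytest.approx(np.std([8.0, 10.0], ddof=1))
        assert summary.years_covered == (2011, 2012)

    @given(st.lists(st.floats(min_value=-30, max_value=30), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_fraction_matches_bruteforce(self, values):
        summary = vt.autumn_summary(dailies_from_values(values), vt.SeasonWindow(), self.WINDOW)
        brute = sum(1 for v in values if 0.0 < v < 15.0) / len(values)
        assert summary.fraction_days_in_window == pytest.approx(brute)


class TestDetectSnowCover:
    def test_synthetic_winter_clamp_detected(self):
        cfg = vt.WeatherConfig(
            season_start="2011-11-01",
            season_end="2012-04-20",
            mean_start_c=2.0,
            mean_end_c=2.0,
            diurnal_amplitude_c=3.0,
            noise_sd_c=2.5,
            snow_onset_date="2011-11-15",
            seed=7,
        )
        series = vt.generate_weather(cfg)
        intervals = vt.detect_snow_cover(series)
        assert len(intervals) >= 1
        clamp_start = pd.Timestamp("2011-11-15")
        clamp_end = series.timestamps[-1]
        clamp_h = (clamp_end - clamp_start).total_seconds() / 3600
        covered = sum(
            (min(e, clamp_end) - max(s, clamp_start)).total_seconds() / 3600
            for s, e in intervals
        )
        assert covered >= 0.95 * clamp_h

    def test_constant_8_no_intervals(self):
        series = make_constant_series(8.0, days=10)
        assert vt.detect_snow_cover(series) == []

    def test_depth_column_shortcut(self):
        ts = pd.date_range("2011-12-01", periods=48, freq="h")
        frame = pd.DataFrame({"timestamp": ts, "temp_c": 0.1, "snow_depth_cm": 12.0})
        series = vt.TemperatureSeries(frame=frame, cadence="hourly")
        intervals = vt.detect_snow_cover(series)
        assert intervals == [(ts[0], ts[-1])]

    def test_short_series_empty(self):
        series = make_constant_series(0.0, days=2)
        assert vt.detect_snow_cover(series) == []

    def test_intervals_disjoint_sorted_and_long_enough(self):
        cfg = vt.WeatherConfig(
            season_start="2011-10-01",
            season_end="2012-03-01",
            mean_start_c=5.0,
            mean_end_c=-5.0,
            snow_onset_date="2011-12-01",
            seed=3,
        )
        series = vt.generate_weather(cfg)
        params = SnowDetectionParams()
        intervals = vt.detect_snow_cover(series, params)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2
        for s, e in intervals:
            assert (e - s).total_seconds() / 3600 >= params.min_run_h
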