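"""Read, validate and summarize temperature/snow records.

Temperature CSV files carry a ``timestamp`` column (ISO 8601, local civil
time), a ``temp_c`` column and an optional ``snow_depth_cm`` column.  Daily
means are built either from hourly traces (logger data) or from the fixed
0600/1200/1800 station readings; autumn-window statistics and snow-cover
detection operate on those products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyInputError, FormatError, InsufficientDataError

__all__ = [
    "TemperatureSeries",
    "SeasonWindow",
    "AutumnSummary",
    "SnowDetectionParams",
    "read_temperature_csv",
    "write_temperature_csv",
    "daily_means",
    "autumn_summary",
    "detect_snow_cover",
]

TEMP_BOUNDS_C = (-60.0, 60.0)

#: Hours (inclusive) of the three fixed station reading times.
STATION_READING_HOURS = (6, 12, 18)

#: Maximum hourly gap (h) that is linearly interpolated before daily aggregation.
MAX_INTERP_GAP_H = 6

#: Minimum raw hourly readings for a day to count as complete.
MIN_HOURS_COMPLETE = 20


@dataclass
class TemperatureSeries:
    """An ordered series of timestamped temperature readings.

    Parameters
    ----------
    frame:
        DataFrame with columns ``timestamp`` (datetime64), ``temp_c`` and
        optionally ``snow_depth_cm``; rows sorted by timestamp, timestamps
        strictly increasing.
    cadence:
        One of ``"hourly"``, ``"thrice_daily"``, ``"irregular"``.
    site_label:
        Free-text provenance label.
    """

    frame: pd.DataFrame
    cadence: str = "irregular"
    site_label: str = ""

    def __post_init__(self) -> None:
        if "timestamp" not in self.frame.columns or "temp_c" not in self.frame.columns:
            raise ContractError("series frame requires 'timestamp' and 'temp_c' columns")
        ts = pd.to_datetime(self.frame["timestamp"])
        if len(ts) and not ts.is_monotonic_increasing:
            raise ContractError("timestamps must be increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise ContractError("timestamps must be strictly increasing (duplicates found)")
        temps = self.frame["temp_c"].to_numpy(dtype=float)
        if len(temps):
            if not np.isfinite(temps).all():
                raise ContractError("temp_c values must be finite")
            lo, hi = TEMP_BOUNDS_C
            if temps.min() < lo or temps.max() > hi:
                raise ContractError(f"temp_c outside plausible bounds {TEMP_BOUNDS_C}")
        snow = self.frame.get("snow_depth_cm")
        if snow is not None and len(snow) and (snow.dropna() < 0).any():
            raise ContractError("snow_depth_cm must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["timestamp"])

    @property
    def temps_c(self) -> np.ndarray:
        return self.frame["temp_c"].to_numpy(dtype=float)

    @property
    def has_snow_depth(self) -> bool:
        return "snow_depth_cm" in self.frame.columns and self.frame["snow_depth_cm"].notna().any()


@dataclass(frozen=True)
class SeasonWindow:
    """A within-year season, default 1 Aug - 30 Nov (inclusive)."""

    start_month_day: tuple[int, int] = (8, 1)
    end_month_day: tuple[int, int] = (11, 30)

    def __post_init__(self) -> None:
        if self.start_month_day >= self.end_month_day:
            raise ContractError("season start must precede season end within one year")

    def contains(self, dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        dates = pd.DatetimeIndex(dates)
        md = list(zip(dates.month, dates.day))
        return np.array([self.start_month_day <= x <= self.end_month_day for x in md])

    @classmethod
    def parse(cls, text: str) -> "SeasonWindow":
        """Parse ``"08-01:11-30"`` into a SeasonWindow."""
        try:
            start, end = text.split(":")
            sm, sd = (int(x) for x in start.split("-"))
            em, ed = (int(x) for x in end.split("-"))
        except ValueError as exc:
            raise FormatError(f"cannot parse season window {text!r}") from exc
        return cls((sm, sd), (em, ed))


@dataclass(frozen=True)
class AutumnSummary:
    """Pooled autumn statistics of daily mean temperatures.

    ``mean_of_daily_means_c`` averages the per-season mean daily temperatures;
    ``sd_of_daily_means_c`` is the SD of those per-season means (within-season
    SD when only one season is present).  ``fraction_days_in_window`` pools all
    complete days and counts daily means strictly inside the window.
    """

    years_covered: tuple[int, ...]
    mean_of_daily_means_c: float
    sd_of_daily_means_c: float
    fraction_days_in_window: float
    window_used: object  # VernalizationWindow; kept loose to avoid an import cycle
    n_days: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_days_in_window <= 1.0):
            raise ContractError("fraction_days_in_window must lie in [0, 1]")
        if self.sd_of_daily_means_c < 0:
            raise ContractError("sd must be >= 0")


@dataclass(frozen=True)
class SnowDetectionParams:
    """Tuning constants for the snow-cover clamp signature."""

    band_c: float = 1.0
    sd_cap_c: float = 0.5
    min_run_h: int = 72
    rolling_window_h: int = 24


def _detect_cadence(ts: pd.DatetimeIndex) -> str:
    if len(ts) < 3:
        return "irregular"
    spacing = np.diff(ts.view("int64")) / 3.6e12  # hours
    if np.isclose(np.median(spacing), 1.0, atol=1e-6):
        return "hourly"
    hours = set(ts.hour)
    minutes = set(ts.minute)
    if hours <= set(STATION_READING_HOURS) and minutes <= {0}:
        return "thrice_daily"
    return "irregular"


def read_temperature_csv(path, cadence_hint: str | None = None) -> TemperatureSeries:
    """Read a temperature CSV into a validated :class:`TemperatureSeries`.

    Rows are sorted by timestamp; duplicated timestamps are collapsed to their
    mean with a warning.  Unparseable timestamps raise :class:`FormatError`
    naming the offending row; an empty file raises :class:`EmptyInputError`.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty input file") from exc
    if raw.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if "timestamp" not in raw.columns or "temp_c" not in raw.columns:
        raise FormatError(f"{path}: header must name 'timestamp' and 'temp_c' columns")

    parsed = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise FormatError(
            f"{path}: unparseable timestamp {raw['timestamp'].iloc[bad]!r} at data row {bad + 1}"
        )
    raw = raw.assign(timestamp=parsed).sort_values("timestamp", kind="stable")

    if raw["timestamp"].duplicated().any():
        n_dup = int(raw["timestamp"].duplicated().sum())
        warnings.warn(
            f"{path}: {n_dup} duplicated timestamp(s) collapsed to their mean",
            stacklevel=2,
        )
        agg = {"temp_c": "mean"}
        if "snow_depth_cm" in raw.columns:
            agg["snow_depth_cm"] = "mean"
        raw = raw.groupby("timestamp", as_index=False).agg(agg)

    cols = ["timestamp", "temp_c"] + (["snow_depth_cm"] if "snow_depth_cm" in raw.columns else [])
    frame = raw[cols].reset_index(drop=True)
    cadence = cadence_hint or _detect_cadence(pd.DatetimeIndex(frame["timestamp"]))
    return TemperatureSeries(frame=frame, cadence=cadence, site_label=str(path))


def write_temperature_csv(series: TemperatureSeries, path, precision: int = 3) -> None:
    """Write a series back to CSV at a fixed decimal precision (round-trip safe)."""
    out = series.frame.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    float_cols = [c for c in out.columns if c != "timestamp"]
    out[float_cols] = out[float_cols].round(precision)
    out.to_csv(path, index=False, float_format=f"%.{precision}f")


def _daily_means_hourly(frame: pd.DataFrame) -> pd.DataFrame:
    ts = pd.DatetimeIndex(frame["timestamp"])
    temps = pd.Series(frame["temp_c"].to_numpy(dtype=float), index=ts)
    # raw readings per civil day, before any gap filling
    n_raw = temps.groupby(temps.index.normalize()).size()
    full = pd.date_range(ts[0].floor("h"), ts[-1].ceil("h"), freq="h")
    on_grid = temps.reindex(full)
    filled = on_grid.interpolate(method="time", limit=MAX_INTERP_GAP_H, limit_area="inside")
    by_day = filled.groupby(filled.index.normalize())
    out = pd.DataFrame(
        {
            "date": by_day.mean().index,
            "daily_mean_c": by_day.mean().to_numpy(),
            "n_readings": n_raw.reindex(by_day.mean().index).fillna(0).astype(int).to_numpy(),
        }
    )
    out["complete"] = (out["n_readings"] >= MIN_HOURS_COMPLETE) & (
        by_day.count().to_numpy() == 24
    )
    return out


def _daily_means_thrice(frame: pd.DataFrame) -> pd.DataFrame:
    ts = pd.DatetimeIndex(frame["timestamp"])
    keep = np.isin(ts.hour, STATION_READING_HOURS) & (ts.minute == 0)
    sub = pd.Series(frame["temp_c"].to_numpy(dtype=float)[keep], index=ts[keep])
    by_day = sub.groupby(sub.index.normalize())
    mean = by_day.mean()
    count = by_day.count()
    return pd.DataFrame(
        {
            "date": mean.index,
            "daily_mean_c": mean.to_numpy(),
            "n_readings": count.to_numpy().astype(int),
            "complete": (count.to_numpy() == len(STATION_READING_HOURS)),
        }
    )


def daily_means(series: TemperatureSeries, policy: str | None = None) -> pd.DataFrame:
    """Aggregate a series into per-day summaries.

    Policy ``"thrice_daily"`` averages the 0600/1200/1800 readings, complete
    only when all three are present.  Policy ``"hourly"`` averages all hourly
    readings after linear interpolation of gaps <= 6 h; complete requires
    >= 20 of 24 raw hours and no unfilled gap.  Incomplete days are flagged,
    never dropped.

    Returns a DataFrame with columns ``date``, ``daily_mean_c``,
    ``n_readings``, ``complete``.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot aggregate an empty series")
    policy = policy or ("thrice_daily" if series.cadence == "thrice_daily" else "hourly")
    if policy == "thrice_daily":
        return _daily_means_thrice(series.frame)
    if policy == "hourly":
        return _daily_means_hourly(series.frame)
    raise ContractError(f"unknown daily-means policy {policy!r}")


def _season_year(dates: pd.DatetimeIndex, season: SeasonWindow) -> np.ndarray:
    # seasons here never straddle new year (invariant of SeasonWindow)
    return dates.year.to_numpy()


def autumn_summary(dailies: pd.DataFrame, season: SeasonWindow, window) -> AutumnSummary:
    """Pool complete in-season days into an :class:`AutumnSummary`.

    ``window`` is a :class:`~vernaltherm.accumulator.VernalizationWindow`;
    membership is strict at both bounds.
    """
    dates = pd.DatetimeIndex(dailies["date"])
    mask = season.contains(dates) & dailies["complete"].to_numpy(dtype=bool)
    if not mask.any():
        raise InsufficientDataError("no complete days fall inside the season window")
    sub = dailies.loc[mask]
    dates = pd.DatetimeIndex(sub["date"])
    means = sub["daily_mean_c"].to_numpy(dtype=float)
    years = _season_year(dates, season)

    per_season = pd.Series(means).groupby(years).mean()
    grand_mean = float(per_season.mean())
    if len(per_season) > 1:
        sd = float(per_season.std(ddof=1))
    else:
        sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0

    inside = (means > window.lower_c) & (means < window.upper_c)
    return AutumnSummary(
        years_covered=tuple(int(y) for y in per_season.index),
        mean_of_daily_means_c=grand_mean,
        sd_of_daily_means_c=sd,
        fraction_days_in_window=float(inside.mean()),
        window_used=window,
        n_days=int(mask.sum()),
    )


def _runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def detect_snow_cover(
    series: TemperatureSeries, params: SnowDetectionParams | None = None
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Find intervals where a soil-surface trace shows the snow-cover clamp.

    A reading is "clamped" when |temp| <= band and the rolling SD <= cap;
    maximal clamped runs of at least ``min_run_h`` become intervals.  When a
    positive ``snow_depth_cm`` column is present, depth > 0 is used directly.
    Returns a sorted list of disjoint (start, end) timestamp pairs.
    """
    params = params or SnowDetectionParams()
    ts = series.timestamps
    if len(ts) == 0:
        return []

    if series.has_snow_depth:
        depth = series.frame["snow_depth_cm"].to_numpy(dtype=float)
        mask = np.nan_to_num(depth, nan=0.0) > 0
        return [(ts[a], ts[b - 1]) for a, b in _runs(mask)]

    span_h = (ts[-1] - ts[0]).total_seconds() / 3600.0
    if span_h < params.min_run_h:
        return []

    temps = pd.Series(series.temps_c, index=ts)
    roll = temps.rolling(f"{params.rolling_window_h}h", min_periods=2)
    rolling_sd = roll.std().bfill()
    mask = (np.abs(temps.to_numpy()) <= params.band_c) & (
        rolling_sd.to_numpy() <= params.sd_cap_c
    )

    intervals = []
    for a, b in _runs(mask):
        start, end = ts[a], ts[b - 1]
        if (end - start).total_seconds() / 3600.0 >= params.min_run_h:
            intervals.append((start, end))
    return intervals
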