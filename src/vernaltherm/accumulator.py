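"""Accumulate vernalization-effective time under configurable temperature windows.

An hour (or a complete day) counts toward vernalization when its temperature
(or daily mean) lies strictly inside the window.  Effective time is expressed
in weeks of 168 h so that hourly and daily-mean bases are commensurable and a
constant in-window reference temperature accumulates linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_io import TemperatureSeries
from .errors import ContractError

__all__ = [
    "HOURS_PER_WEEK",
    "DAYTIME_HOURS",
    "VernalizationWindow",
    "AccumulationTrace",
    "accumulate",
    "reference_accumulation",
    "weeks_to_saturation",
]

HOURS_PER_WEEK = 168.0

#: Civil hours treated as "daytime" when a window is restricted to daylight,
#: matching an 8 h photoperiod (08:00 inclusive to 16:00 exclusive).
DAYTIME_HOURS = (8, 16)


@dataclass(frozen=True)
class VernalizationWindow:
    """An open temperature interval defining effective vernalization.

    ``basis`` selects whether membership is evaluated per hourly reading or
    per complete-day mean; ``daytime_only`` (hourly basis only) restricts
    counting to the civil daylight hours in :data:`DAYTIME_HOURS`.
    Membership is strict at both bounds.
    """

    lower_c: float
    upper_c: float
    basis: str = "hourly"
    daytime_only: bool = False

    def __post_init__(self) -> None:
        if not self.lower_c < self.upper_c:
            raise ContractError("window requires lower_c < upper_c")
        if self.basis not in ("hourly", "daily_mean"):
            raise ContractError(f"unknown basis {self.basis!r}")
        if self.daytime_only and self.basis != "hourly":
            raise ContractError("daytime_only requires basis='hourly'")

    def contains(self, temp_c) -> np.ndarray:
        temp_c = np.asarray(temp_c, dtype=float)
        return (temp_c > self.lower_c) & (temp_c < self.upper_c)

    @classmethod
    def parse(cls, text: str, basis: str = "hourly", daytime_only: bool = False):
        """Parse ``"0:15"`` into a window."""
        lo, hi = (float(x) for x in text.split(":"))
        return cls(lo, hi, basis=basis, daytime_only=daytime_only)


@dataclass
class AccumulationTrace:
    """Cumulative effective vernalization time along a record.

    ``effective_time_h`` is non-decreasing; ``effective_weeks`` is
    ``effective_time_h / 168`` and never exceeds ``reference_weeks``, the
    accumulation a constant in-window reference temperature would achieve.
    """

    timestamps: pd.DatetimeIndex
    effective_time_h: np.ndarray
    reference_weeks: np.ndarray
    window: VernalizationWindow
    reference_temp_c: float

    def __post_init__(self) -> None:
        self.effective_time_h = np.asarray(self.effective_time_h, dtype=float)
        self.reference_weeks = np.asarray(self.reference_weeks, dtype=float)
        if np.any(np.diff(self.effective_time_h) < 0):
            raise ContractError("effective_time_h must be non-decreasing")

    @property
    def effective_weeks(self) -> np.ndarray:
        return self.effective_time_h / HOURS_PER_WEEK

    @property
    def total_effective_weeks(self) -> float:
        return float(self.effective_weeks[-1]) if len(self.effective_time_h) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "effective_weeks": self.effective_weeks,
                "reference_weeks": self.reference_weeks,
            }
        )


def _accumulate_hourly(series: TemperatureSeries, window: VernalizationWindow):
    ts = series.timestamps
    temps = series.temps_c
    hit = window.contains(temps)
    if window.daytime_only:
        lo, hi = DAYTIME_HOURS
        hit &= (ts.hour >= lo) & (ts.hour < hi)
    effective = np.cumsum(hit.astype(float))  # each reading stands for one hour
    elapsed_h = np.arange(1, len(ts) + 1, dtype=float)
    return ts, effective, elapsed_h


def _accumulate_daily(dailies: pd.DataFrame, window: VernalizationWindow):
    dates = pd.DatetimeIndex(dailies["date"])
    means = dailies["daily_mean_c"].to_numpy(dtype=float)
    complete = dailies["complete"].to_numpy(dtype=bool)
    hit = window.contains(means) & complete  # incomplete days contribute nothing
    effective = np.cumsum(np.where(hit, 24.0, 0.0))
    elapsed_h = 24.0 * np.arange(1, len(dates) + 1, dtype=float)
    return dates, effective, elapsed_h


def accumulate(data, window: VernalizationWindow, reference_temp_c: float = 8.0) -> AccumulationTrace:
    """Accumulate effective hours from ``data`` under ``window``.

    ``data`` must be an hourly :class:`TemperatureSeries` for hourly basis, or
    a daily-summary DataFrame (from :func:`vernaltherm.climate_io.daily_means`)
    for daily-mean basis; a mismatch raises :class:`ContractError`.  The
    companion reference line assumes ``reference_temp_c`` (which must lie
    inside the window) held constant over the same span.
    """
    if window.basis == "hourly":
        if not isinstance(data, TemperatureSeries):
            raise ContractError("hourly basis requires a TemperatureSeries")
        if data.cadence != "hourly":
            raise ContractError(f"hourly basis requires hourly cadence, got {data.cadence!r}")
        ts, effective, elapsed_h = _accumulate_hourly(data, window)
    else:
        if isinstance(data, TemperatureSeries):
            raise ContractError("daily_mean basis requires daily summaries, not a raw series")
        if "daily_mean_c" not in data.columns:
            raise ContractError("daily_mean basis requires a daily-summary frame")
        ts, effective, elapsed_h = _accumulate_daily(data, window)

    if not window.contains(reference_temp_c):
        raise ContractError(
            f"reference temperature {reference_temp_c} lies outside window "
            f"({window.lower_c}, {window.upper_c})"
        )
    return AccumulationTrace(
        timestamps=ts,
        effective_time_h=effective,
        reference_weeks=elapsed_h / HOURS_PER_WEEK,
        window=window,
        reference_temp_c=reference_temp_c,
    )


def reference_accumulation(start, end, reference_temp_c: float, window: VernalizationWindow) -> float:
    """Weeks accumulated by a constant ``reference_temp_c`` between two instants.

    The reference must lie strictly inside the window (otherwise it would
    accumulate nothing, contradicting its role as the attainable maximum).
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ContractError("start must not follow end")
    if not window.contains(reference_temp_c):
        raise ContractError("reference temperature must lie inside the window")
    return (end - start).total_seconds() / 3600.0 / HOURS_PER_WEEK


def weeks_to_saturation(trace: AccumulationTrace, required_weeks: float):
    """First timestamp at which the trace reaches ``required_weeks``, else None."""
    if required_weeks <= 0:
        raise ContractError("required_weeks must be > 0")
    reached = np.flatnonzero(trace.effective_weeks >= required_weeks)
    if len(reached) == 0:
        return None
    return trace.timestamps[int(reached[0])]
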