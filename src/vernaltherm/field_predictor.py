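"""Predict field transplant flowering from cabinet response surfaces.

The prediction procedure mirrors the constant-condition matching idea: the
mean temperature of the sow-to-transfer interval is computed from the field
temperature record, the nearest cabinet (temperature, duration) condition is
selected, and that cell's flowering-time summary becomes the prediction.
Bilinear interpolation is available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_io import TemperatureSeries
from .errors import ContractError, InsufficientDataError
from .response_surface import ResponseSurface, interpolate

__all__ = [
    "FieldCohort",
    "FieldPrediction",
    "interval_mean_temperature",
    "match_constant_condition",
    "predict_cohort",
    "evaluate_predictions",
    "cohorts_from_frame",
]

#: Minimum fraction of an interval that must be covered by readings.
MIN_COVERAGE = 0.8

#: Cells with prop_dnf above this are propagated as DNF predictions.
DNF_FLAG_LEVEL = 0.5


@dataclass(frozen=True)
class FieldCohort:
    """A transplant cohort: sown in the field, moved to warm on a fixed date."""

    genotype: str
    sow_date: pd.Timestamp
    transfer_date: pd.Timestamp
    observed_dtf: tuple[float, ...]
    dnf_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sow_date", pd.Timestamp(self.sow_date))
        object.__setattr__(self, "transfer_date", pd.Timestamp(self.transfer_date))
        if self.transfer_date <= self.sow_date:
            raise ContractError("transfer_date must follow sow_date")
        if len(self.observed_dtf) + self.dnf_count < 1:
            raise ContractError("cohort needs >= 1 replicate")

    @property
    def observed_mean_dtf(self) -> float:
        return float(np.mean(self.observed_dtf)) if self.observed_dtf else float("nan")


@dataclass(frozen=True)
class FieldPrediction:
    cohort: FieldCohort
    interval_mean_temp_c: float
    interval_duration_weeks: float
    matched_cabinet_temp_c: float
    matched_cabinet_duration_weeks: float
    predicted_dtf: float
    predicted_dnf: bool
    observed_mean_dtf: float
    residual: float
    matched_cell_sd: float = float("nan")
    matched_cell_n: int = 0
    mode: str = "match"


def cohorts_from_frame(frame: pd.DataFrame) -> list[FieldCohort]:
    """Group a replicate-level cohort CSV frame into :class:`FieldCohort` objects."""
    needed = {"genotype", "sow_date", "transfer_date", "days_to_flower", "dnf"}
    missing = needed - set(frame.columns)
    if missing:
        raise ContractError(f"cohort frame missing columns {sorted(missing)}")
    out = []
    for (g, sow, transfer), grp in frame.groupby(
        ["genotype", "sow_date", "transfer_date"], sort=True
    ):
        dnf = grp["dnf"].astype(bool)
        out.append(
            FieldCohort(
                genotype=str(g),
                sow_date=pd.Timestamp(sow),
                transfer_date=pd.Timestamp(transfer),
                observed_dtf=tuple(grp.loc[~dnf, "days_to_flower"].astype(float)),
                dnf_count=int(dnf.sum()),
            )
        )
    return out


def interval_mean_temperature(series: TemperatureSeries, start, end) -> float:
    """Time-weighted mean temperature over [start, end).

    Uses trapezoidal integration over the (possibly irregular) readings, with
    linear interpolation at the interval boundaries.  Raises
    :class:`InsufficientDataError` when readings cover less than 80% of the
    interval.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start >= end:
        raise ContractError("start must precede end")
    ts = series.timestamps
    temps = series.temps_c
    inside = (ts >= start) & (ts <= end)
    if inside.sum() < 2:
        raise InsufficientDataError("fewer than two readings inside the interval")

    t_in = ts[inside]
    span = (end - start).total_seconds()
    covered = (min(t_in[-1], end) - max(t_in[0], start)).total_seconds()
    # internal gaps beyond 3 h also count as uncovered
    gaps = np.diff(t_in.view("int64")) / 1e9
    covered -= float(gaps[gaps > 3 * 3600].sum())
    if covered / span < MIN_COVERAGE:
        raise InsufficientDataError(
            f"readings cover {covered / span:.0%} of the interval (< {MIN_COVERAGE:.0%})"
        )

    sec = ts.view("int64").astype(float) / 1e9
    lo, hi = sec[0], sec[-1]
    a = float(np.clip(start.value / 1e9, lo, hi))
    b = float(np.clip(end.value / 1e9, lo, hi))
    grid = np.unique(np.concatenate((sec[(sec >= a) & (sec <= b)], [a, b])))
    vals = np.interp(grid, sec, temps)
    return float(np.trapezoid(vals, grid) / (grid[-1] - grid[0]))


def match_constant_condition(
    mean_temp_c: float, duration_weeks: float, surface: ResponseSurface
) -> tuple[float, float]:
    """Nearest cabinet condition to a field (mean temperature, duration).

    Ties resolve toward the lower temperature and the shorter duration.
    """
    temps = surface.temps_c
    durs = surface.durations_weeks
    if len(temps) == 0 or len(durs) == 0:
        raise ContractError("surface grid is empty")
    # argmin returns the first (lowest) index on ties because grids are sorted
    t = float(temps[int(np.argmin(np.abs(temps - mean_temp_c)))])
    d = float(durs[int(np.argmin(np.abs(durs - duration_weeks)))])
    return t, d


def predict_cohort(
    cohort: FieldCohort,
    series: TemperatureSeries,
    surface: ResponseSurface,
    mode: str = "match",
) -> FieldPrediction:
    """Predict a cohort's flowering time from the field record and a surface.

    ``mode='match'`` uses the nearest cabinet cell's mean (the constant-
    condition matching procedure); ``mode='interpolate'`` uses bilinear
    interpolation at the exact interval mean and duration.  The two agree
    whenever the interval lands exactly on a grid node.
    """
    if mode not in ("match", "interpolate"):
        raise ContractError(f"unknown mode {mode!r}")
    if surface.genotype != cohort.genotype:
        raise ContractError(
            f"surface is for {surface.genotype!r}, cohort is {cohort.genotype!r}"
        )
    mean_temp = interval_mean_temperature(series, cohort.sow_date, cohort.transfer_date)
    weeks = (cohort.transfer_date - cohort.sow_date).total_seconds() / 3600.0 / 168.0

    t_m, d_m = match_constant_condition(mean_temp, weeks, surface)
    i = int(np.flatnonzero(surface.temps_c == t_m)[0])
    j = int(np.flatnonzero(surface.durations_weeks == d_m)[0])

    if mode == "match":
        predicted = float(surface.mean_dtf[i, j])
        predicted_dnf = bool(surface.prop_dnf[i, j] > DNF_FLAG_LEVEL)
    else:
        res = interpolate(surface, mean_temp, weeks)
        predicted = res.mean_dtf
        predicted_dnf = bool(res.dnf_risk > DNF_FLAG_LEVEL)

    observed = cohort.observed_mean_dtf
    return FieldPrediction(
        cohort=cohort,
        interval_mean_temp_c=mean_temp,
        interval_duration_weeks=weeks,
        matched_cabinet_temp_c=t_m,
        matched_cabinet_duration_weeks=d_m,
        predicted_dtf=predicted,
        predicted_dnf=predicted_dnf,
        observed_mean_dtf=observed,
        residual=observed - predicted,
        matched_cell_sd=float(surface.sd_dtf[i, j]),
        matched_cell_n=int(surface.n[i, j]),
        mode=mode,
    )


def evaluate_predictions(predictions) -> dict:
    """Summarize prediction residuals per genotype and pooled.

    Returns a dict with a per-genotype DataFrame (bias, MAE, n), pooled bias
    and MAE, and a 2x2 DNF concordance table (predicted x observed).
    """
    predictions = list(predictions)
    if not predictions:
        raise ContractError("need >= 1 prediction")
    rows = []
    for p in predictions:
        obs_dnf = p.cohort.dnf_count > (len(p.cohort.observed_dtf))
        rows.append(
            {
                "genotype": p.cohort.genotype,
                "residual": p.residual,
                "predicted_dnf": p.predicted_dnf,
                "observed_dnf": obs_dnf,
            }
        )
    frame = pd.DataFrame(rows)
    resid = frame["residual"].astype(float)
    per_genotype = (
        frame.groupby("genotype")["residual"]
        .agg(bias="mean", mae=lambda r: r.abs().mean(), n="count")
        .reset_index()
    )
    concordance = pd.crosstab(
        frame["predicted_dnf"], frame["observed_dnf"], dropna=False
    ).reindex(index=[False, True], columns=[False, True], fill_value=0)
    return {
        "per_genotype": per_genotype,
        "pooled_bias": float(resid.mean()),
        "pooled_mae": float(resid.abs().mean()),
        "dnf_concordance": concordance,
        "n": len(frame),
    }
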