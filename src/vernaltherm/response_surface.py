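"""Genotype flowering-time response surfaces over (temperature, duration).

A surface summarizes replicated cabinet experiments on a rectangular grid of
constant vernalization temperatures crossed with cold durations (weeks),
including the non-vernalized (duration 0) control.  Queries are answered by
bilinear interpolation; the optimum temperature and the effective temperature
range are derived from the fitted cell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, NoOptimumError, NoRangeError

__all__ = [
    "FloweringRecord",
    "ResponseSurface",
    "EffectiveRange",
    "InterpolationResult",
    "fit_surface",
    "fit_surfaces",
    "interpolate",
    "optimal_temperature",
    "effective_range",
    "surface_to_frame",
    "surface_from_frame",
]

RECORD_COLUMNS = ["genotype", "temp_c", "duration_weeks", "replicate_id", "days_to_flower", "dnf"]

#: Cells with more than this DNF proportion are excluded from optimum search.
DNF_DOMINATED = 0.5


@dataclass(frozen=True)
class FloweringRecord:
    """A single replicate's flowering-time observation.

    ``days_to_flower`` counts days of growth after return to warm until floral
    buds are visible; for DNF replicates it records the censoring bound (the
    last day scored).
    """

    genotype: str
    temp_c: float
    duration_weeks: float
    replicate_id: str
    days_to_flower: float
    dnf: bool = False

    def __post_init__(self) -> None:
        if self.duration_weeks < 0:
            raise ContractError("duration_weeks must be >= 0")
        if not self.dnf and self.days_to_flower <= 0:
            raise ContractError("days_to_flower must be > 0 unless DNF")


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise ContractError(f"record frame missing columns {missing}")
        return records
    return pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)


@dataclass
class ResponseSurface:
    """Fitted per-cell summaries on a rectangular (temperature, duration) grid.

    All 2-D arrays are indexed ``[temperature, duration]``.  Cells that were
    never attempted carry ``n == 0`` and NaN summaries; cells where every
    replicate failed to flower carry NaN ``mean_dtf`` with ``prop_dnf == 1``.
    """

    genotype: str
    temps_c: np.ndarray
    durations_weeks: np.ndarray
    mean_dtf: np.ndarray
    sd_dtf: np.ndarray
    n: np.ndarray
    prop_dnf: np.ndarray

    def __post_init__(self) -> None:
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        self.durations_weeks = np.asarray(self.durations_weeks, dtype=float)
        shape = (len(self.temps_c), len(self.durations_weeks))
        for name in ("mean_dtf", "sd_dtf", "n", "prop_dnf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ContractError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if np.any(np.diff(self.temps_c) <= 0) or np.any(np.diff(self.durations_weeks) <= 0):
            raise ContractError("grid axes must be strictly increasing")
        if 0.0 not in self.durations_weeks:
            raise ContractError("surface requires the duration-0 (NV) condition")

    @property
    def nv_mean_dtf(self) -> float:
        """Mean days-to-flower of the non-vernalized control, pooled over temps."""
        j = int(np.flatnonzero(self.durations_weeks == 0.0)[0])
        col_means = self.mean_dtf[:, j]
        col_n = self.n[:, j] * (1.0 - self.prop_dnf[:, j])
        ok = np.isfinite(col_means) & (col_n > 0)
        if not ok.any():
            return float("nan")
        return float(np.average(col_means[ok], weights=col_n[ok]))


@dataclass(frozen=True)
class EffectiveRange:
    """Contiguous temperature span where the vernalization effect exceeds a criterion."""

    genotype: str
    t_low_c: float
    t_high_c: float
    criterion_fraction: float
    duration_weeks_used: float
    clamped_low: bool = False
    clamped_high: bool = False

    def __post_init__(self) -> None:
        if self.t_low_c > self.t_high_c:
            raise ContractError("t_low_c must not exceed t_high_c")


@dataclass(frozen=True)
class InterpolationResult:
    mean_dtf: float
    dnf_risk: float


def fit_surface(records, genotype: str | None = None) -> ResponseSurface:
    """Summarize flowering records into a :class:`ResponseSurface`.

    Cell means and SDs are taken over non-DNF replicates; DNF replicates are
    carried as ``prop_dnf``.  A missing duration-0 condition is a contract
    error.  When ``records`` spans several genotypes, ``genotype`` selects one.
    """
    frame = records_to_frame(records)
    if genotype is not None:
        frame = frame[frame["genotype"] == genotype]
    genotypes = frame["genotype"].unique()
    if len(genotypes) != 1:
        raise ContractError(f"fit_surface needs exactly one genotype, got {list(genotypes)}")
    if frame.empty:
        raise ContractError("no records to fit")
    if not (frame["duration_weeks"] == 0).any():
        raise ContractError("records lack the duration-0 (NV) condition")

    temps = np.sort(frame["temp_c"].unique())
    durs = np.sort(frame["duration_weeks"].unique())
    shape = (len(temps), len(durs))
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    n = np.zeros(shape)
    pdnf = np.full(shape, np.nan)

    ti = {t: i for i, t in enumerate(temps)}
    dj = {d: j for j, d in enumerate(durs)}
    for (t, d), cell in frame.groupby(["temp_c", "duration_weeks"]):
        i, j = ti[t], dj[d]
        dnf = cell["dnf"].astype(bool)
        flowered = cell.loc[~dnf, "days_to_flower"].to_numpy(dtype=float)
        n[i, j] = len(cell)
        pdnf[i, j] = float(dnf.mean())
        if len(flowered):
            mean[i, j] = float(flowered.mean())
            sd[i, j] = float(flowered.std(ddof=1)) if len(flowered) > 1 else 0.0

    return ResponseSurface(
        genotype=str(genotypes[0]),
        temps_c=temps,
        durations_weeks=durs,
        mean_dtf=mean,
        sd_dtf=sd,
        n=n,
        prop_dnf=pdnf,
    )


def fit_surfaces(records) -> dict[str, ResponseSurface]:
    """Fit one surface per genotype present in ``records``."""
    frame = records_to_frame(records)
    return {g: fit_surface(sub) for g, sub in frame.groupby("genotype")}


def _bracket(grid: np.ndarray, x: float) -> tuple[int, int, float]:
    """Indices (i0, i1) bracketing x and the linear weight toward i1."""
    i1 = int(np.searchsorted(grid, x))
    i1 = min(max(i1, 1), len(grid) - 1)
    i0 = i1 - 1
    if grid[i0] == x:  # exact node (also handles x == grid[0])
        return i0, i0, 0.0
    if grid[i1] == x:
        return i1, i1, 0.0
    w = (x - grid[i0]) / (grid[i1] - grid[i0])
    return i0, i1, float(w)


def _bilinear(grid_x, grid_y, values, x, y) -> float:
    i0, i1, wx = _bracket(grid_x, x)
    j0, j1, wy = _bracket(grid_y, y)
    v00, v10 = values[i0, j0], values[i1, j0]
    v01, v11 = values[i0, j1], values[i1, j1]
    return float(
        (1 - wx) * (1 - wy) * v00
        + wx * (1 - wy) * v10
        + (1 - wx) * wy * v01
        + wx * wy * v11
    )


def interpolate(surface: ResponseSurface, temp_c: float, duration_weeks: float) -> InterpolationResult:
    """Bilinear interpolation of cell means and DNF risk at an off-grid query.

    Exact at grid nodes.  Queries outside the grid are clamped to its bounds
    with a warning.  Requires at least a 2 x 2 grid.
    """
    if len(surface.temps_c) < 2 or len(surface.durations_weeks) < 2:
        raise ContractError("interpolation requires >= 2 temperatures and >= 2 durations")
    t, d = float(temp_c), float(duration_weeks)
    t_clamped = float(np.clip(t, surface.temps_c[0], surface.temps_c[-1]))
    d_clamped = float(np.clip(d, surface.durations_weeks[0], surface.durations_weeks[-1]))
    if t_clamped != t or d_clamped != d:
        warnings.warn(
            f"query ({t}, {d}) outside grid; clamped to ({t_clamped}, {d_clamped})",
            stacklevel=2,
        )
    mean = _bilinear(surface.temps_c, surface.durations_weeks, surface.mean_dtf, t_clamped, d_clamped)
    risk = _bilinear(surface.temps_c, surface.durations_weeks, surface.prop_dnf, t_clamped, d_clamped)
    return InterpolationResult(mean_dtf=mean, dnf_risk=risk)


def optimal_temperature(
    surface: ResponseSurface, duration_weeks: float, max_prop_dnf: float = DNF_DOMINATED
) -> float:
    """Grid temperature minimizing mean days-to-flower at ``duration_weeks``.

    DNF-dominated cells (``prop_dnf > max_prop_dnf``) are excluded; exact ties
    resolve to the lower temperature and are reported via a warning.
    """
    durs = surface.durations_weeks
    if duration_weeks not in durs:
        raise ContractError(f"duration {duration_weeks} not in grid {list(durs)}")
    j = int(np.flatnonzero(durs == duration_weeks)[0])
    means = surface.mean_dtf[:, j].copy()
    means[~np.isfinite(means)] = np.inf
    means[surface.prop_dnf[:, j] > max_prop_dnf] = np.inf
    if not np.isfinite(means).any():
        raise NoOptimumError(f"all cells at duration {duration_weeks} are DNF-dominated")
    best = means.min()
    tied = surface.temps_c[means == best]
    if len(tied) > 1:
        warnings.warn(f"optimum tied among temperatures {list(tied)}; reporting lowest", stacklevel=2)
    return float(tied[0])


def effective_range(
    surface: ResponseSurface, duration_weeks: float, criterion_fraction: float = 0.5
) -> EffectiveRange:
    """Temperature span where the normalized vernalization effect exceeds a criterion.

    The effect at temperature T is the flowering-time reduction relative to
    the NV control, ``nv_mean - mean(T, d)``, normalized by its maximum over
    temperatures.  The returned range is the contiguous span around the
    optimum, with the criterion crossings located by linear interpolation;
    when the effect still exceeds the criterion at a grid edge the range is
    clamped there and flagged.
    """
    if not 0.0 < criterion_fraction <= 1.0:
        raise ContractError("criterion_fraction must lie in (0, 1]")
    if len(surface.temps_c) < 3:
        raise ContractError("effective_range requires >= 3 grid temperatures")
    nv = surface.nv_mean_dtf
    if not np.isfinite(nv):
        raise ContractError("NV mean unavailable")
    durs = surface.durations_weeks
    if duration_weeks not in durs:
        raise ContractError(f"duration {duration_weeks} not in grid {list(durs)}")
    j = int(np.flatnonzero(durs == duration_weeks)[0])

    temps = surface.temps_c
    effect = nv - surface.mean_dtf[:, j]
    effect = np.where(np.isfinite(effect), effect, 0.0)
    max_effect = effect.max()
    if max_effect <= 0:
        raise NoRangeError("no cell shows a positive vernalization effect")
    rel = effect / max_effect
    k = int(np.argmax(rel))

    # walk outward from the optimum; strict "exceeds" so criterion 1.0 degenerates
    lo = hi = k
    while lo > 0 and rel[lo - 1] > criterion_fraction:
        lo -= 1
    while hi < len(temps) - 1 and rel[hi + 1] > criterion_fraction:
        hi += 1

    if rel[k] <= criterion_fraction:  # only possible at criterion 1.0 exactly
        t_low = t_high = float(temps[k])
        clamp_lo = clamp_hi = False
    else:
        if lo == 0:
            t_low, clamp_lo = float(temps[0]), True
        else:
            r0, r1 = rel[lo - 1], rel[lo]
            t_low = float(temps[lo - 1] + (temps[lo] - temps[lo - 1]) * (criterion_fraction - r0) / (r1 - r0))
            clamp_lo = False
        if hi == len(temps) - 1:
            t_high, clamp_hi = float(temps[-1]), True
        else:
            r0, r1 = rel[hi], rel[hi + 1]
            t_high = float(temps[hi] + (temps[hi + 1] - temps[hi]) * (criterion_fraction - r0) / (r1 - r0))
            clamp_hi = False

    return EffectiveRange(
        genotype=surface.genotype,
        t_low_c=t_low,
        t_high_c=t_high,
        criterion_fraction=criterion_fraction,
        duration_weeks_used=float(duration_weeks),
        clamped_low=clamp_lo,
        clamped_high=clamp_hi,
    )


def surface_to_frame(surface: ResponseSurface) -> pd.DataFrame:
    """One row per grid cell, suitable for CSV round-tripping."""
    rows = []
    for i, t in enumerate(surface.temps_c):
        for j, d in enumerate(surface.durations_weeks):
            rows.append(
                {
                    "genotype": surface.genotype,
                    "temp_c": t,
                    "duration_weeks": d,
                    "mean_dtf": surface.mean_dtf[i, j],
                    "sd_dtf": surface.sd_dtf[i, j],
                    "n": int(surface.n[i, j]),
                    "prop_dnf": surface.prop_dnf[i, j],
                }
            )
    return pd.DataFrame(rows)


def surface_from_frame(frame: pd.DataFrame, genotype: str | None = None) -> ResponseSurface:
    """Rebuild a surface from its per-cell CSV representation."""
    if genotype is not None:
        frame = frame[frame["genotype"] == genotype]
    genotypes = frame["genotype"].unique()
    if len(genotypes) != 1:
        raise ContractError(f"surface frame needs exactly one genotype, got {list(genotypes)}")
    temps = np.sort(frame["temp_c"].unique())
    durs = np.sort(frame["duration_weeks"].unique())
    shape = (len(temps), len(durs))
    arrays = {k: np.full(shape, np.nan) for k in ("mean_dtf", "sd_dtf", "n", "prop_dnf")}
    arrays["n"] = np.zeros(shape)
    ti = {t: i for i, t in enumerate(temps)}
    dj = {d: j for j, d in enumerate(durs)}
    for _, row in frame.iterrows():
        i, j = ti[row["temp_c"]], dj[row["duration_weeks"]]
        for k in arrays:
            arrays[k][i, j] = row[k]
    return ResponseSurface(
        genotype=str(genotypes[0]), temps_c=temps, durations_weeks=durs, **arrays
    )
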