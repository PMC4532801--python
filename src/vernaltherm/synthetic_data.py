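"""Synthetic weather traces and flowering-time datasets with known ground truth.

Every generator is a pure function of its configuration and seed, so each
downstream stage (daily aggregation, window accumulation, surface fitting,
field prediction) can be tested against the parameters that produced its
input rather than against opaque fixtures.

The flowering-time ground truth combines a temperature-effectiveness kernel
with saturating (Hill-type) progress in duration:

    K(T) = exp(-(T - t_opt)^2 / (2 sigma^2))   for t_min < T < t_max, else 0
    P(T, d) = (d K)^h / ((d K)^h + full_weeks^h)
    DTF(T, d) = nv_dtf - (nv_dtf - sat_dtf) * P

so DTF falls from the non-vernalized baseline toward the saturated value as
effective cold accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate_io import TemperatureSeries
from .errors import ContractError

__all__ = [
    "WeatherConfig",
    "GenotypeParams",
    "GENOTYPE_PRESETS",
    "DEFAULT_TEMPS_C",
    "DEFAULT_DURATIONS_WEEKS",
    "generate_weather",
    "true_dtf",
    "generate_flowering",
    "generate_field_experiment",
]

#: Cabinet design defaults: 7 constant temperatures x 4 cold durations.
DEFAULT_TEMPS_C = (0.0, 2.0, 5.0, 8.0, 10.0, 12.0, 14.0)
DEFAULT_DURATIONS_WEEKS = (0.0, 4.0, 6.0, 12.0)


@dataclass(frozen=True)
class WeatherConfig:
    """Configuration of the hourly autumn weather generator.

    The generated trace is a linear seasonal trend from ``mean_start_c`` to
    ``mean_end_c`` plus a sinusoidal diurnal cycle (peaking mid-afternoon)
    plus AR(1) noise; after ``snow_onset_date`` the trace is clamped to
    ``snow_clamp_c`` with small jitter, mimicking the soil-surface signature
    of insulating snow.
    """

    season_start: str = "2011-08-01"
    season_end: str = "2011-11-30"
    mean_start_c: float = 14.0
    mean_end_c: float = 0.0
    diurnal_amplitude_c: float = 3.0
    noise_sd_c: float = 2.5
    noise_autocorr: float = 0.8
    snow_onset_date: str | None = None
    snow_clamp_c: float = 0.0
    snow_clamp_jitter_c: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ContractError("noise_autocorr must lie in [0, 1)")
        if self.noise_sd_c < 0:
            raise ContractError("noise_sd_c must be >= 0")
        if pd.Timestamp(self.season_start) >= pd.Timestamp(self.season_end):
            raise ContractError("season_start must precede season_end")


@dataclass(frozen=True)
class GenotypeParams:
    """Parametric ground truth for one genotype's vernalization response."""

    genotype: str
    nv_dtf: float = 140.0
    sat_dtf: float = 40.0
    t_opt_c: float = 8.0
    kernel_sd_c: float = 4.0
    t_min_c: float = 0.0
    t_max_c: float = 15.0
    full_weeks: float = 8.0
    hill_h: float = 2.0
    rep_noise_sd: float = 10.0
    dnf_threshold_dtf: float = 200.0

    def __post_init__(self) -> None:
        if not self.sat_dtf < self.nv_dtf:
            raise ContractError("sat_dtf must be < nv_dtf")
        if not self.t_min_c < self.t_opt_c < self.t_max_c:
            raise ContractError("need t_min_c < t_opt_c < t_max_c")
        if self.full_weeks <= 0:
            raise ContractError("full_weeks must be > 0")


# Qualitative stand-ins for the five cabinet genotypes: a broadly responsive
# reference pair, a slow-saturating southern type, and two with a marked
# optimum near 8 degrees.  Labelled synthetic throughout; never measured data.
GENOTYPE_PRESETS: dict[str, GenotypeParams] = {
    "synth-colfri": GenotypeParams(
        "synth-colfri", nv_dtf=130.0, sat_dtf=35.0, t_opt_c=5.0, kernel_sd_c=4.0,
        t_min_c=0.0, t_max_c=16.0, full_weeks=6.0, hill_h=2.0, rep_noise_sd=9.5,
    ),
    "synth-edi": GenotypeParams(
        "synth-edi", nv_dtf=125.0, sat_dtf=38.0, t_opt_c=5.0, kernel_sd_c=4.5,
        t_min_c=0.0, t_max_c=16.0, full_weeks=6.0, hill_h=2.0, rep_noise_sd=8.7,
    ),
    "synth-ull": GenotypeParams(
        "synth-ull", nv_dtf=135.0, sat_dtf=40.0, t_opt_c=5.0, kernel_sd_c=5.0,
        t_min_c=0.0, t_max_c=16.0, full_weeks=12.0, hill_h=2.0, rep_noise_sd=9.5,
    ),
    "synth-var": GenotypeParams(
        "synth-var", nv_dtf=140.0, sat_dtf=42.0, t_opt_c=7.0, kernel_sd_c=3.0,
        t_min_c=0.0, t_max_c=15.0, full_weeks=10.0, hill_h=2.0, rep_noise_sd=9.8,
    ),
    "synth-lov": GenotypeParams(
        "synth-lov", nv_dtf=150.0, sat_dtf=45.0, t_opt_c=8.0, kernel_sd_c=4.0,
        t_min_c=0.0, t_max_c=15.0, full_weeks=12.0, hill_h=2.0, rep_noise_sd=10.5,
    ),
}


def generate_weather(config: WeatherConfig) -> TemperatureSeries:
    """Generate an hourly autumn temperature trace from ``config``.

    Deterministic per (config, seed); the returned series has hourly cadence
    covering every hour from midnight on ``season_start`` through 23:00 on
    ``season_end`` inclusive.
    """
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end) + pd.Timedelta(hours=23)
    ts = pd.date_range(start, end, freq="h")
    n = len(ts)
    frac = np.arange(n) / max(n - 1, 1)
    trend = config.mean_start_c + (config.mean_end_c - config.mean_start_c) * frac
    diurnal = config.diurnal_amplitude_c * np.sin(2 * np.pi * (ts.hour.to_numpy() - 9) / 24.0)

    rng = np.random.default_rng(config.seed)
    rho = config.noise_autocorr
    innov_sd = config.noise_sd_c * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    prev = rng.normal(0.0, config.noise_sd_c) if config.noise_sd_c > 0 else 0.0
    for i in range(n):
        prev = rho * prev + eps[i]
        noise[i] = prev

    temps = trend + diurnal + noise
    if config.snow_onset_date is not None:
        onset = pd.Timestamp(config.snow_onset_date)
        clamped = ts >= onset
        jitter = rng.normal(0.0, config.snow_clamp_jitter_c, size=int(clamped.sum()))
        temps[clamped] = config.snow_clamp_c + jitter

    frame = pd.DataFrame({"timestamp": ts, "temp_c": np.clip(temps, -59.9, 59.9)})
    return TemperatureSeries(frame=frame, cadence="hourly", site_label="synthetic")


def true_dtf(params: GenotypeParams, temp_c, duration_weeks):
    """Ground-truth mean days-to-flower at a constant (temperature, duration)."""
    t = np.asarray(temp_c, dtype=float)
    d = np.asarray(duration_weeks, dtype=float)
    kernel = np.where(
        (t > params.t_min_c) & (t < params.t_max_c),
        np.exp(-((t - params.t_opt_c) ** 2) / (2.0 * params.kernel_sd_c**2)),
        0.0,
    )
    x = np.maximum(d * kernel, 0.0) ** params.hill_h
    progress = np.where(x > 0, x / (x + params.full_weeks**params.hill_h), 0.0)
    out = params.nv_dtf - (params.nv_dtf - params.sat_dtf) * progress
    return float(out) if out.ndim == 0 else out


def generate_flowering(
    params_set,
    temps_c=DEFAULT_TEMPS_C,
    durations_weeks=DEFAULT_DURATIONS_WEEKS,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a replicated cabinet experiment over a full design grid.

    Latent replicate DTF is truth plus Gaussian noise; latent values above the
    genotype's DNF threshold are censored (``dnf = 1`` with ``days_to_flower``
    recording the threshold).  Returns a record frame with columns
    ``genotype, temp_c, duration_weeks, replicate_id, days_to_flower, dnf``.
    """
    if n_reps < 1:
        raise ContractError("n_reps must be >= 1")
    if isinstance(params_set, GenotypeParams):
        params_set = [params_set]
    rng = np.random.default_rng(seed)
    rows = []
    for params in params_set:
        for t in temps_c:
            for d in durations_weeks:
                truth = true_dtf(params, t, d)
                latent = truth + rng.normal(0.0, params.rep_noise_sd, size=n_reps)
                for r, val in enumerate(latent):
                    dnf = bool(val > params.dnf_threshold_dtf)
                    rows.append(
                        {
                            "genotype": params.genotype,
                            "temp_c": float(t),
                            "duration_weeks": float(d),
                            "replicate_id": f"{params.genotype}-T{t}-D{d}-r{r}",
                            "days_to_flower": float(
                                params.dnf_threshold_dtf if dnf else max(val, 1.0)
                            ),
                            "dnf": dnf,
                        }
                    )
    return pd.DataFrame(rows)


def generate_field_experiment(
    weather_config: WeatherConfig,
    params_set,
    sow_date,
    transfer_dates,
    n_reps: int = 10,
    seed: int = 0,
):
    """Simulate a transplant experiment consistent with its own weather trace.

    Observed cohort DTF values are drawn around the ground truth evaluated at
    the sow-to-transfer interval's mean temperature and duration, so that
    prediction from the same truth is recoverable.  Returns ``(series,
    cohorts)`` where ``cohorts`` is a record frame with columns ``genotype,
    sow_date, transfer_date, replicate_id, days_to_flower, dnf``.
    """
    if isinstance(params_set, GenotypeParams):
        params_set = [params_set]
    series = generate_weather(weather_config)
    ts = series.timestamps
    sow = pd.Timestamp(sow_date)
    rng = np.random.default_rng(seed)

    rows = []
    for transfer in transfer_dates:
        transfer = pd.Timestamp(transfer)
        if transfer < ts[0] or transfer > ts[-1] + pd.Timedelta(hours=1):
            raise ContractError(f"transfer date {transfer} outside the weather span")
        in_interval = (ts >= sow) & (ts < transfer)
        weeks = (transfer - sow).total_seconds() / 3600.0 / 168.0
        mean_temp = float(series.temps_c[in_interval].mean()) if in_interval.any() else np.nan
        for params in params_set:
            truth = (
                params.nv_dtf if weeks == 0 else true_dtf(params, mean_temp, weeks)
            )
            latent = truth + rng.normal(0.0, params.rep_noise_sd, size=n_reps)
            for r, val in enumerate(latent):
                dnf = bool(val > params.dnf_threshold_dtf)
                rows.append(
                    {
                        "genotype": params.genotype,
                        "sow_date": sow,
                        "transfer_date": transfer,
                        "replicate_id": f"{params.genotype}-{transfer.date()}-r{r}",
                        "days_to_flower": float(
                            params.dnf_threshold_dtf if dnf else max(val, 1.0)
                        ),
                        "dnf": dnf,
                    }
                )
    return series, pd.DataFrame(rows)
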