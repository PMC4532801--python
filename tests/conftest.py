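import numpy as np
import pandas as pd
import pytest

import vernaltherm as vt
from vernaltherm.synthetic_data import GENOTYPE_PRESETS


def make_constant_series(temp_c=8.0, days=14, start="2011-09-01", freq="h"):
    ts = pd.date_range(start, periods=days * (24 if freq == "h" else 1), freq=freq)
    frame = pd.DataFrame({"timestamp": ts, "temp_c": float(temp_c)})
    return vt.TemperatureSeries(frame=frame, cadence="hourly" if freq == "h" else "irregular")


def make_constant_dailies(temp_c=8.0, days=84, start="2011-09-01"):
    dates = pd.date_range(start, periods=days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "daily_mean_c": float(temp_c),
            "n_readings": 24,
            "complete": True,
        }
    )


@pytest.fixture(scope="session")
def autumn_series():
    """Default synthetic northern-autumn hourly trace, seed 1."""
    return vt.generate_weather(vt.WeatherConfig(seed=1))


@pytest.fixture(scope="session")
def autumn_dailies(autumn_series):
    return vt.daily_means(autumn_series)


@pytest.fixture(scope="session")
def lov_params():
    return GENOTYPE_PRESETS["synth-lov"]


@pytest.fixture(scope="session")
def lov_surface(lov_params):
    """Fitted surface from one seeded cabinet simulation of the lov-like preset."""
    records = vt.generate_flowering(lov_params, n_reps=10, seed=11)
    return vt.fit_surface(records)


# Calibrated synthetic transplant design: the linear seasonal trend passes
# through 12C at the 4-week interval midpoint and 5C at the 12-week midpoint,
# so interval means land on cabinet grid temperatures in expectation.
FIELD_TREND = dict(mean_start_c=23.25, mean_end_c=-7.3, noise_sd_c=1.2, noise_autocorr=0.8)
FIELD_TRANSFER_WEEKS = (4, 6, 12)


def make_field_experiment(trial_seed, years=(2011, 2012), n_field=60, n_cabinet=10):
    """Two-year transplant simulation sharing one cabinet-fitted surface set."""
    params = list(GENOTYPE_PRESETS.values())
    surfaces = vt.fit_surfaces(
        vt.generate_flowering(params, n_reps=n_cabinet, seed=trial_seed * 1000 + 20)
    )
    runs = []
    for year_i, year in enumerate(years):
        seed = trial_seed * 1000 + year_i
        cfg = vt.WeatherConfig(
            season_start=f"{year}-08-01", season_end=f"{year}-12-01", seed=seed, **FIELD_TREND
        )
        sow = pd.Timestamp(f"{year}-09-01")
        transfers = [sow + pd.Timedelta(weeks=w) for w in FIELD_TRANSFER_WEEKS]
        series, cohorts = vt.generate_field_experiment(
            cfg, params, sow, transfers, n_reps=n_field, seed=seed + 10
        )
        runs.append((year, series, cohorts))
    return surfaces, runs


@pytest.fixture(scope="session")
def field_experiment():
    return make_field_experiment(trial_seed=28)
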