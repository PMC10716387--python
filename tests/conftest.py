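"""Shared fixtures: one canonical synthetic world with a known truth,
fitted once per session and reused by recovery, uncertainty, and
projection tests."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from thermoburden import ccfit, curves, splines, synth
from thermoburden.pipeline import RunConfig

# Canonical per-stage seeds derived from master seed 0, exactly as the
# pipeline derives them.
SEEDS = RunConfig(seed=0).stage_seeds()


@dataclass
class World:
    weather: pd.DataFrame
    temps: np.ndarray
    surface: synth.TrueSurface
    deaths: pd.DataFrame
    spec: splines.CrossBasisSpec
    design: ccfit.DesignMatrix
    model: ccfit.FittedModel
    curve: curves.ReducedCurve


def build_world(
    weather_seed: int,
    death_seed: int,
    expected_deaths: float = 30_000.0,
    start: str = "2013-01-01",
    end: str = "2019-12-31",
) -> World:
    """Simulate one study world and fit the case-crossover DLNM."""
    weather = synth.simulate_weather(
        synth.WeatherParams(start, end, seed=weather_seed)
    )
    temps = weather["temp_c"].to_numpy()
    surface = synth.default_surface(temps)
    # baseline rate chosen so the expected death count is `expected_deaths`
    f = surface.exposure_log_rr(temps)
    n = len(temps)
    log_rel = np.zeros(n)
    for lag, wt in enumerate(surface.lag_weights):
        log_rel[14:] += wt * f[14 - lag : n - lag]
    baseline = expected_deaths / np.exp(log_rel[14:]).sum()
    deaths = synth.simulate_deaths(weather, surface, baseline_rate=baseline, seed=death_seed)
    spec = splines.CrossBasisSpec.default(temps)
    cb = splines.build_crossbasis(temps, spec)
    design = ccfit.build_design(weather, cb)
    strata, dropped = ccfit.build_strata(deaths["date"], design.usable_days)
    model = ccfit.fit_conditional_logistic(strata, design, n_dropped=dropped)
    curve = curves.find_mmt(curves.reduce_overall(model, spec), temps)
    return World(weather, temps, surface, deaths, spec, design, model, curve)


@pytest.fixture(scope="session")
def recovery_world() -> World:
    """Seven years of weather, ~30,000 deaths from the default inverted-J
    truth, and the full conditional-logistic DLNM fit."""
    return build_world(SEEDS["weather"], SEEDS["deaths"])


@pytest.fixture(scope="session")
def small_world() -> World:
    """A cheaper two-year world (~5,000 deaths) for tests that only need
    a plausible fitted model."""
    return build_world(
        SEEDS["weather"], SEEDS["deaths"], expected_deaths=5_000.0, end="2014-12-31"
    )
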