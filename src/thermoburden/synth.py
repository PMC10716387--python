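"""Synthetic weather, mortality, and climate-scenario generators.

These generators emulate the three data streams a temperature-mortality
projection study needs but cannot ship: a daily observational weather
series (seasonal cycle plus AR(1) noise), individual death records whose
daily hazard follows a known exposure-lag-response surface over lags
0-14, and per-GCM scenario temperature series over 1980-2099 with an
additive model bias and a scenario-dependent warming ramp.  Because the
true surface is known, estimator recovery and burden-projection behaviour
can be verified end to end.

Output schemas (CSV):

* weather  -- ``date,temp_c,rh_pct,holiday``
* deaths   -- ``id,date,cause,age_group,sex,education,region``
* scenario -- ``date,gcm,scenario,temp_c``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherParams",
    "TrueSurface",
    "ScenarioParams",
    "simulate_weather",
    "simulate_deaths",
    "simulate_scenario_series",
    "default_surface",
    "DEFAULT_DEMOGRAPHICS",
]

MAX_LAG = 14

# Fixed synthetic holiday calendar: ten dates per year, plus weekends.
_HOLIDAY_DATES = (
    (1, 1), (2, 10), (4, 5), (5, 1), (6, 22),
    (9, 8), (10, 1), (10, 2), (10, 3), (12, 25),
)

# Attribute distributions loosely matching a national neurodegenerative
# death registry: dominated by ages >= 65, slight female majority, mostly
# lower education.  Sampled independently of temperature by construction.
DEFAULT_DEMOGRAPHICS: Mapping[str, Mapping[str, float]] = {
    "age_group": {"<=64": 0.078, "65-74": 0.25, ">=75": 0.672},
    "sex": {"female": 0.535, "male": 0.465},
    "education": {"junior_or_less": 0.916, "high_or_above": 0.084},
    "region": {"national": 1.0},
}


@dataclass(frozen=True)
class WeatherParams:
    """Configuration of the observational weather generator.

    ``daily_sd`` is the standard deviation of the AR(1) innovations (degrees
    Celsius); the stationary SD of the noise is ``daily_sd/sqrt(1-ar1**2)``.
    A zero ``daily_sd`` is accepted and yields a noise-free series, which
    some degenerate checks rely on.
    """

    start_date: str
    end_date: str
    mean_temp: float = 13.5
    seasonal_amplitude: float = 14.0
    ar1_coef: float = 0.7
    daily_sd: float = 2.5
    humidity_mean: float = 70.0
    humidity_sd: float = 12.0
    seed: int = 0
    peak_doy: int = 196  # mid-July: northern-hemisphere summer peak

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end_date) <= pd.Timestamp(self.start_date):
            raise ValueError(
                f"end_date {self.end_date!r} must be after start_date {self.start_date!r}"
            )
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.daily_sd < 0:
            raise ValueError("daily_sd must be non-negative")


@dataclass(frozen=True)
class TrueSurface:
    """Known exposure-lag-response surface driving the death hazard.

    ``exposure_log_rr`` maps temperature to the cumulative log relative
    risk versus ``reference_temp`` (where it must vanish); ``lag_weights``
    distribute that cumulative effect over lags 0..14 and sum to one.
    """

    exposure_log_rr: Callable[[np.ndarray], np.ndarray]
    lag_weights: np.ndarray
    reference_temp: float

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        object.__setattr__(self, "lag_weights", w)
        if w.shape != (MAX_LAG + 1,):
            raise ValueError(f"lag_weights must have length {MAX_LAG + 1}")
        if (w < 0).any():
            raise ValueError("lag_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("lag_weights must sum to 1")
        ref = float(np.asarray(self.exposure_log_rr(np.array([self.reference_temp])))[0])
        if abs(ref) > 1e-9:
            raise ValueError("exposure_log_rr must vanish at reference_temp")


def default_surface(
    temps: Sequence[float],
    rr_cold: float = 2.0,
    rr_heat: float = 1.3,
    reference_percentile: float = 75.0,
    lag_pattern: str = "heat",
) -> TrueSurface:
    """Piecewise-quadratic inverted-J surface anchored to a temperature sample.

    The reference sits at the ``reference_percentile`` of ``temps``; the
    cumulative RR rises smoothly to ``rr_cold`` at the 2.5th percentile and
    ``rr_heat`` at the 97.5th, mirroring the magnitudes typical of national
    cold/heat mortality associations.  ``lag_pattern`` selects front-loaded
    weights (heat-like, geometric decay) or back-loaded weights peaking
    mid-lag (cold-like).
    """
    arr = np.asarray(temps, dtype=float)
    p025, ref, p975 = np.quantile(arr, [0.025, reference_percentile / 100.0, 0.975])
    a_cold = np.log(rr_cold) / (p025 - ref) ** 2
    a_heat = np.log(rr_heat) / (p975 - ref) ** 2

    def log_rr(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = t - ref
        return np.where(d < 0, a_cold * d**2, a_heat * d**2)

    if lag_pattern == "heat":
        w = 0.55**np.arange(MAX_LAG + 1)
    elif lag_pattern == "cold":
        lags = np.arange(MAX_LAG + 1, dtype=float)
        w = np.exp(-0.5 * ((lags - 6.0) / 3.0) ** 2)
    else:
        raise ValueError(f"unknown lag_pattern {lag_pattern!r}")
    return TrueSurface(log_rr, w / w.sum(), float(ref))


@dataclass(frozen=True)
class ScenarioParams:
    """One emission scenario for the synthetic GCM ensemble.

    ``warming_by_2090s`` is the target difference between the 2090s
    decadal-mean temperature and the zero-ramp historical climatology;
    defaults for the three standard scenarios are in
    :data:`SCENARIO_DEFAULTS`.
    """

    scenario_id: str
    warming_by_2090s: float
    gcm_bias_offset: float = 1.5
    gcm_variance_scale: float = 1.0
    n_gcms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be >= 1")
        if self.gcm_variance_scale <= 0:
            raise ValueError("gcm_variance_scale must be > 0")


# National-mean warming by the 2090s relative to the historical period
# under strict-mitigation, intermediate, and unrestricted-emission futures.
SCENARIO_DEFAULTS: Mapping[str, float] = {"SSP126": 1.9, "SSP245": 2.9, "SSP585": 5.4}


def _holiday_flags(index: pd.DatetimeIndex) -> np.ndarray:
    weekend = index.dayofweek >= 5
    fixed = np.zeros(len(index), dtype=bool)
    md = list(zip(index.month, index.day))
    for m, d in _HOLIDAY_DATES:
        fixed |= np.array([t == (m, d) for t in md])
    return (weekend | fixed).astype(int)


def simulate_weather(params: WeatherParams) -> pd.DataFrame:
    """Daily weather: seasonal cosine + AR(1) noise, humidity, holidays.

    Returns a DataFrame indexed by date with columns ``temp_c``,
    ``rh_pct``, ``holiday``.  Deterministic given ``params.seed``.
    """
    index = pd.date_range(params.start_date, params.end_date, freq="D")
    rng = np.random.default_rng(params.seed)
    doy = index.dayofyear.to_numpy(dtype=float)
    seasonal = params.mean_temp + params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - params.peak_doy) / 365.25
    )
    n = len(index)
    noise = np.zeros(n)
    innov = rng.normal(0.0, params.daily_sd, size=n) if params.daily_sd > 0 else np.zeros(n)
    for t in range(1, n):
        noise[t] = params.ar1_coef * noise[t - 1] + innov[t]
    noise[0] = innov[0]
    rh = np.clip(rng.normal(params.humidity_mean, params.humidity_sd, size=n), 0.0, 100.0)
    return pd.DataFrame(
        {
            "temp_c": seasonal + noise,
            "rh_pct": rh,
            "holiday": _holiday_flags(index),
        },
        index=index,
    )


def _sample_categories(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(dist)
    probs = np.array([dist[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def simulate_deaths(
    weather: pd.DataFrame,
    surface: TrueSurface,
    baseline_rate: float,
    demographics_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    cause: str = "neurodegenerative",
) -> pd.DataFrame:
    """Draw death records from a Poisson hazard driven by lagged temperature.

    The expected count on day ``t`` is
    ``baseline_rate * exp(sum_l w[l] * f(T[t-l]))``; deaths occur only on
    days with a complete 14-day exposure history, so the first eligible
    death date is ``weather start + 14 days``.
    """
    if len(weather) <= MAX_LAG:
        raise ValueError(
            f"weather series must cover at least {MAX_LAG + 1} days before deaths can occur"
        )
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be non-negative")
    demo = demographics_spec if demographics_spec is not None else DEFAULT_DEMOGRAPHICS
    rng = np.random.default_rng(seed)
    temps = weather["temp_c"].to_numpy(dtype=float)
    f = np.asarray(surface.exposure_log_rr(temps), dtype=float)
    n = len(temps)
    log_rel = np.zeros(n)
    for lag, w in enumerate(surface.lag_weights):
        log_rel[MAX_LAG:] += w * f[MAX_LAG - lag : n - lag]
    rate = baseline_rate * np.exp(log_rel)
    rate[:MAX_LAG] = 0.0
    counts = rng.poisson(rate)
    dates = np.repeat(weather.index.to_numpy(), counts)
    total = int(counts.sum())
    records = {"id": np.arange(total), "date": dates, "cause": np.full(total, cause, dtype=object)}
    for attr, dist in demo.items():
        records[attr] = _sample_categories(rng, dist, total)
    return pd.DataFrame(records)


def _year_fraction(index: pd.DatetimeIndex) -> np.ndarray:
    origin = pd.Timestamp("1980-01-01")
    return 1980.0 + (index - origin).days.to_numpy(dtype=float) / 365.25


def warming_ramp(index: pd.DatetimeIndex, warming_by_2090s: float) -> np.ndarray:
    """Linear warming ramp: zero through 2009, rising from 2010 so that the
    2090s decadal mean equals ``warming_by_2090s`` (attained at mid-decade,
    year 2095.0)."""
    yf = _year_fraction(index)
    return warming_by_2090s * np.clip((yf - 2010.0) / (2095.0 - 2010.0), 0.0, None)


def simulate_scenario_series(
    obs: pd.DataFrame,
    params: ScenarioParams,
    start: str = "1980-01-01",
    end: str = "2099-12-31",
) -> pd.DataFrame:
    """Per-GCM daily temperature series over the projection horizon.

    Each GCM resamples the observational day-of-year climatology (so model
    variability tracks observed variability), scales anomalies about the
    seasonal mean by ``gcm_variance_scale``, then adds the constant model
    bias and the scenario warming ramp.  The historical segment
    (1980-2009) carries no ramp.  Returns tidy rows
    ``date,gcm,scenario,temp_c``.
    """
    if len(obs) < 366:
        raise ValueError("observational series too short to build a day-of-year climatology")
    index = pd.date_range(start, end, freq="D")
    obs_temp = obs["temp_c"].to_numpy(dtype=float)
    obs_doy = obs.index.dayofyear.to_numpy()
    # day-of-year pools (+-3-day window) and their means
    pools: dict[int, np.ndarray] = {}
    for d in range(1, 367):
        mask = np.abs(((obs_doy - d + 183) % 366) - 183) <= 3
        pools[d] = obs_temp[mask]
    clim_mean = {d: p.mean() for d, p in pools.items()}
    ramp = warming_ramp(index, params.warming_by_2090s)
    doy = index.dayofyear.to_numpy()
    mu = np.array([clim_mean[d] for d in doy])
    frames = []
    rng = np.random.default_rng(params.seed)
    for g in range(params.n_gcms):
        draws = np.array([pools[d][rng.integers(len(pools[d]))] for d in doy])
        temp = mu + params.gcm_variance_scale * (draws - mu) + params.gcm_bias_offset + ramp
        frames.append(
            pd.DataFrame(
                {
                    "date": index,
                    "gcm": f"GCM{g:02d}",
                    "scenario": params.scenario_id,
                    "temp_c": temp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Plain-text I/O helpers


def write_weather(weather: pd.DataFrame, path) -> None:
    out = weather.reset_index(names="date")
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df.set_index("date")


def write_deaths(deaths: pd.DataFrame, path) -> None:
    out = deaths.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_deaths(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_scenario(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_scenario(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
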