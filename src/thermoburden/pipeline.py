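"""Desk-scale study orchestration: simulate -> fit -> reduce -> calibrate
-> attribute -> report, driven by a YAML config with one master seed.

Per-stage seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence.spawn`` in a fixed order (weather, deaths,
scenarios, Monte-Carlo), so every output table is reproducible from the
config alone.  Each run writes a manifest recording the config hash and
the derived seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribute, calibrate, ccfit, curves, splines, synth

__all__ = ["RunConfig", "run_simulate", "run_association", "run_projection"]


@dataclass
class RunConfig:
    """Plain-text run configuration (see ``RunConfig.from_yaml``)."""

    outdir: str = "run"
    seed: int = 0
    # simulation
    weather_start: str = "2013-01-01"
    weather_end: str = "2019-12-31"
    obs_start: str = "1980-01-01"
    obs_end: str = "2014-12-31"
    baseline_rate: float = 12.0
    rr_cold: float = 2.0
    rr_heat: float = 1.3
    lag_pattern: str = "heat"
    flat_surface: bool = False
    scenarios: dict = field(
        default_factory=lambda: dict(synth.SCENARIO_DEFAULTS)
    )
    n_gcms: int = 5
    gcm_bias_offset: float = 1.5
    # association
    subgroup: str | None = None  # pandas query over death records
    # projection
    n_sim: int = 1000
    decades: tuple = attribute.SCENARIO_DECADES
    overlap: tuple = ("1980-01-01", "2009-12-31")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("weather", "deaths", "scenario", "mc")
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(config: RunConfig, out: Path, stage: str, extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "stage_seeds": config.stage_seeds(),
        "config_hash": config.config_hash(),
        **(extra or {}),
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate weather, deaths, and per-scenario GCM series as CSVs."""
    out = _outdir(config)
    seeds = config.stage_seeds()
    weather = synth.simulate_weather(
        synth.WeatherParams(
            start_date=config.weather_start,
            end_date=config.weather_end,
            seed=seeds["weather"],
        )
    )
    temps = weather["temp_c"].to_numpy()
    if config.flat_surface:
        surface = synth.TrueSurface(
            lambda t: np.zeros_like(np.asarray(t, dtype=float)),
            np.full(15, 1.0 / 15.0),
            float(np.median(temps)),
        )
    else:
        surface = synth.default_surface(
            temps, rr_cold=config.rr_cold, rr_heat=config.rr_heat, lag_pattern=config.lag_pattern
        )
    deaths = synth.simulate_deaths(weather, surface, config.baseline_rate, seed=seeds["deaths"])
    obs = synth.simulate_weather(
        synth.WeatherParams(
            start_date=config.obs_start, end_date=config.obs_end, seed=seeds["weather"]
        )
    )
    paths = {"weather": out / "weather.csv", "deaths": out / "deaths.csv", "obs": out / "obs.csv"}
    synth.write_weather(weather, paths["weather"])
    synth.write_deaths(deaths, paths["deaths"])
    synth.write_weather(obs, paths["obs"])
    for sid, warming in config.scenarios.items():
        series = synth.simulate_scenario_series(
            obs,
            synth.ScenarioParams(
                scenario_id=sid,
                warming_by_2090s=warming,
                gcm_bias_offset=config.gcm_bias_offset,
                n_gcms=config.n_gcms,
                seed=seeds["scenario"],
            ),
        )
        p = out / f"scenario_{sid}.csv"
        synth.write_scenario(series, p)
        paths[f"scenario_{sid}"] = p
    _write_manifest(config, out, "simulate", {"true_reference_temp": float(surface.reference_temp)})
    return paths


def run_association(config: RunConfig) -> dict:
    """Fit the case-crossover DLNM and export curve/RR artifacts."""
    out = _outdir(config)
    weather = synth.read_weather(out / "weather.csv")
    deaths = synth.read_deaths(out / "deaths.csv")
    if config.subgroup:
        deaths = deaths.query(config.subgroup)
    temps = weather["temp_c"].to_numpy()
    spec = splines.CrossBasisSpec.default(temps)
    cb = splines.build_crossbasis(temps, spec)
    design = ccfit.build_design(weather, cb)
    strata, dropped = ccfit.build_strata(deaths["date"], design.usable_days)
    model = ccfit.fit_conditional_logistic(strata, design, n_dropped=dropped)
    if not model.converged:
        raise RuntimeError(f"association fit failed: {model.message}")
    curve = curves.reduce_overall(model, spec)
    curve = curves.find_mmt(curve, temps)
    p025, p975 = np.percentile(temps, [2.5, 97.5])
    rr_table = pd.DataFrame(
        [
            {
                "quantity": "MMT_c",
                "value": curve.tmm,
                "ci_low": np.nan,
                "ci_high": np.nan,
            },
            *(
                {
                    "quantity": f"RR_P{label}",
                    "value": est.rr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
                for label, est in (
                    ("2.5", curves.rr_at(curve, p025)),
                    ("97.5", curves.rr_at(curve, p975)),
                )
            ),
        ]
    )
    rr_table.to_csv(out / "rr_table.csv", index=False)
    curves.curve_frame(curve).to_csv(out / "overall_curve.csv", index=False)
    for label, t in (("heat", p975), ("cold", p025)):
        curves.lag_response_at(model, spec, t, curve.tmm).to_csv(
            out / f"lag_response_{label}.csv", index=False
        )
    artifact = {
        "coef": model.coef.tolist(),
        "vcov": model.vcov.tolist(),
        "columns": model.columns,
        "n_crossbasis": model.n_crossbasis,
        "spec": spec.to_dict(),
        "n_strata": model.n_strata,
        "n_dropped_strata": model.n_dropped,
        "loglik": model.loglik,
        "tmm": curve.tmm,
        "mmt_on_boundary": curve.mmt_on_boundary,
        "display_range": list(curve.display_range),
        "reduced_coef": curve.coef.tolist(),
        "reduced_vcov": curve.vcov.tolist(),
        "baseline_daily_deaths": float(len(deaths) / len(weather)),
    }
    with open(out / "model.json", "w") as fh:
        json.dump(artifact, fh, indent=2)
    _write_manifest(
        config,
        out,
        "associate",
        {"n_strata": model.n_strata, "n_dropped_strata": model.n_dropped},
    )
    return artifact


def load_curve(artifact: dict) -> curves.ReducedCurve:
    spec = splines.CrossBasisSpec.from_dict(artifact["spec"])
    return curves.ReducedCurve(
        coef=np.asarray(artifact["reduced_coef"]),
        vcov=np.asarray(artifact["reduced_vcov"]),
        exposure_spec=spec.exposure_spec,
        tmm=artifact["tmm"],
        mmt_on_boundary=artifact["mmt_on_boundary"],
        display_range=tuple(artifact["display_range"]),
    )


def run_projection(config: RunConfig, n_sim: int | None = None) -> dict[str, pd.DataFrame]:
    """Calibrate scenario series and project the burden tables."""
    out = _outdir(config)
    with open(out / "model.json") as fh:
        artifact = json.load(fh)
    curve = load_curve(artifact)
    D = artifact["baseline_daily_deaths"]
    obs = synth.read_weather(out / "obs.csv")
    seeds = config.stage_seeds()
    n_sim = config.n_sim if n_sim is None else n_sim
    burdens, diffs = [], []
    for sid in config.scenarios:
        series = synth.read_scenario(out / f"scenario_{sid}.csv")
        # each GCM gets its own correction, fitted on the historical overlap
        corrected_frames = []
        for gcm, grp in series.groupby("gcm", sort=True):
            grp = grp.set_index("date")
            corr = calibrate.fit_correction(
                obs, grp.loc[config.overlap[0] : config.overlap[1]], overlap=config.overlap
            )
            fixed = calibrate.apply_correction(
                grp, corr, reference_period=config.overlap
            ).reset_index()
            corrected_frames.append(fixed)
        corrected = pd.concat(corrected_frames, ignore_index=True)
        burden, diff = attribute.project_burden(
            curve,
            corrected,
            D,
            decades=config.decades,
            n_sim=n_sim,
            seed=seeds["mc"],
        )
        burdens.append(burden)
        diffs.append(diff)
    burden_all = pd.concat(burdens, ignore_index=True)
    diff_all = pd.concat(diffs, ignore_index=True)
    burden_all.to_csv(out / "burden.csv", index=False)
    diff_all.to_csv(out / "burden_differences.csv", index=False)
    _write_manifest(config, out, "project", {"n_sim": n_sim})
    return {"burden": burden_all, "differences": diff_all}
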