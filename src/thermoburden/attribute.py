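"""Attributable deaths and fractions under projected temperatures.

Daily attributable deaths follow ``D * (1 - exp(-delta))`` where
``delta`` is the cumulative log relative risk of the day's temperature
versus the minimum-mortality temperature and ``D`` the average daily
death count of the observation period.  Days above the MMT contribute to
the heat component, days below to the cold component; sums are taken by
GCM and decade, ensemble-averaged, and expressed as fractions of total
deaths.  Uncertainty is propagated by Monte-Carlo resampling of the
reduced-curve coefficients (MMT held at its point estimate), pooling
draws across GCMs, and taking empirical 2.5th/97.5th percentiles.
Differences versus the 1980-2009 historical baseline are computed inside
each draw so their empirical intervals are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import ReducedCurve
from .splines import natural_cubic_basis

__all__ = [
    "HISTORICAL_DECADES",
    "SCENARIO_DECADES",
    "daily_attributable",
    "decade_burden",
    "mc_eci",
    "difference_vs_historical",
    "project_burden",
]

HISTORICAL_DECADES = ("1980s", "1990s", "2000s")
SCENARIO_DECADES = tuple(f"{d}s" for d in range(2010, 2100, 10))
_COMPONENTS = ("heat", "cold", "net")


def decade_of(dates: pd.DatetimeIndex) -> np.ndarray:
    years = pd.DatetimeIndex(dates).year.to_numpy()
    return np.char.add((years // 10 * 10).astype(str), "s")


def _contrast(curve: ReducedCurve, temps: np.ndarray) -> np.ndarray:
    if curve.tmm is None:
        raise ValueError("curve has no minimum-mortality temperature set")
    B = natural_cubic_basis(temps, curve.exposure_spec)
    return B - natural_cubic_basis(float(curve.tmm), curve.exposure_spec)


def daily_attributable(curve: ReducedCurve, temps, D: float) -> np.ndarray:
    """Attributable deaths per day: ``D * (1 - exp(-delta))``.

    Positive on days away from the MMT, exactly zero at the MMT.  Values
    are signed (a temperature with fitted RR below 1 relative to the MMT
    yields a negative contribution) and deliberately not truncated.
    """
    if D < 0:
        raise ValueError("baseline daily deaths D must be non-negative")
    temps = np.atleast_1d(np.asarray(temps, dtype=float))
    delta = _contrast(curve, temps) @ curve.coef
    return D * (1.0 - np.exp(-delta))


def _component_sums(an: np.ndarray, heat_mask: np.ndarray) -> dict[str, float]:
    heat = float(an[heat_mask].sum())
    cold = float(an[~heat_mask].sum())
    return {"heat": heat, "cold": cold, "net": heat + cold}


def _draw_coefs(curve: ReducedCurve, n_sim: int, seed) -> np.ndarray:
    """Multivariate-normal coefficient draws (eigen square root; PSD-safe)."""
    vals, vecs = np.linalg.eigh(curve.vcov)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise ValueError("reduced covariance is not positive semidefinite")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sim, len(curve.coef)))
    return curve.coef + z @ root.T


def _decade_frame(series: pd.DataFrame, decade: str) -> pd.DataFrame:
    sel = series[decade_of(pd.DatetimeIndex(series["date"])) == decade]
    if sel.empty:
        raise ValueError(f"scenario series does not cover decade {decade!r}")
    return sel


def decade_burden(
    curve: ReducedCurve,
    series: pd.DataFrame,
    D: float,
    decade: str,
    region: str = "national",
    cause: str = "neurodegenerative",
) -> pd.DataFrame:
    """Point-estimate burden for one decade: GCM-ensemble averages.

    ``series`` is the tidy per-GCM frame (``date,gcm,scenario,temp_c``).
    Heat sums days strictly above the MMT, cold the rest (the MMT day
    itself contributes exactly zero either way).  AN is the ensemble mean
    of per-GCM decade sums; AF = AN / (D * days in decade) * 100.
    """
    sel = _decade_frame(series, decade)
    scenario = str(sel["scenario"].iloc[0])
    per_gcm = {c: [] for c in _COMPONENTS}
    n_days = None
    for _, grp in sel.groupby("gcm", sort=True):
        temps = grp["temp_c"].to_numpy(dtype=float)
        n_days = len(temps)
        an = daily_attributable(curve, temps, D)
        sums = _component_sums(an, temps > curve.tmm)
        for c in _COMPONENTS:
            per_gcm[c].append(sums[c])
    total_deaths = D * n_days
    rows = []
    for c in _COMPONENTS:
        an_mean = float(np.mean(per_gcm[c]))
        rows.append(
            {
                "region": region,
                "cause": cause,
                "scenario": scenario,
                "decade": decade,
                "component": c,
                "an": an_mean,
                "af_pct": 100.0 * an_mean / total_deaths,
            }
        )
    return pd.DataFrame(rows)


def _an_draws(
    curve: ReducedCurve,
    series: pd.DataFrame,
    D: float,
    decade: str,
    coef_draws: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-(draw, GCM) decade AN sums for each component.

    Returns arrays of shape ``(n_sim, n_gcms)``.
    """
    sel = _decade_frame(series, decade)
    out = {c: [] for c in _COMPONENTS}
    for _, grp in sel.groupby("gcm", sort=True):
        temps = grp["temp_c"].to_numpy(dtype=float)
        M = _contrast(curve, temps)  # (days, k)
        delta = M @ coef_draws.T  # (days, n_sim)
        an = D * (1.0 - np.exp(-delta))
        heat = temps > curve.tmm
        h = an[heat].sum(axis=0)
        cold = an[~heat].sum(axis=0)
        out["heat"].append(h)
        out["cold"].append(cold)
        out["net"].append(h + cold)
    return {c: np.column_stack(v) for c, v in out.items()}


def mc_eci(
    curve: ReducedCurve,
    series: pd.DataFrame,
    D: float,
    decade: str,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Empirical 95% CIs for one decade's AN/AF by Monte-Carlo resampling.

    Coefficients are redrawn ``n_sim`` times from the reduced curve's
    sampling distribution with the MMT fixed at its point estimate; the
    per-draw, per-GCM decade sums are pooled and their 2.5th/97.5th
    percentiles reported.  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    draws = _draw_coefs(curve, n_sim, seed)
    pooled = _an_draws(curve, series, D, decade, draws)
    n_days = len(_decade_frame(series, decade)) // pooled["heat"].shape[1]
    total = D * n_days
    rows = []
    for c in _COMPONENTS:
        flat = pooled[c].ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "decade": decade,
                "component": c,
                "eci_low": float(lo),
                "eci_high": float(hi),
                "af_eci_low": 100.0 * float(lo) / total,
                "af_eci_high": 100.0 * float(hi) / total,
            }
        )
    return pd.DataFrame(rows)


def difference_vs_historical(
    cells: pd.DataFrame,
    historical_cells: pd.DataFrame,
) -> pd.DataFrame:
    """Point-estimate differences versus the historical-baseline average.

    The baseline per component is the mean over the historical decades
    (1980-2009); differences are reported for every scenario decade
    present in ``cells``.  Net differences equal the sum of the heat and
    cold differences.
    """
    for col in ("component", "an", "af_pct"):
        if col not in cells or col not in historical_cells:
            raise ValueError(f"burden frames must carry a {col!r} column")
    base = historical_cells.groupby("component")[["an", "af_pct"]].mean()
    rows = []
    for _, row in cells.iterrows():
        if row["component"] not in base.index:
            raise ValueError(f"no historical baseline for component {row['component']!r}")
        b = base.loc[row["component"]]
        rows.append(
            {
                **{k: row[k] for k in ("region", "cause", "scenario", "decade", "component")},
                "d_an": row["an"] - b["an"],
                "d_af_pct": row["af_pct"] - b["af_pct"],
            }
        )
    return pd.DataFrame(rows)


def project_burden(
    curve: ReducedCurve,
    series: pd.DataFrame,
    D: float,
    decades=SCENARIO_DECADES,
    historical_decades=HISTORICAL_DECADES,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    region: str = "national",
    cause: str = "neurodegenerative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full burden projection for one scenario series.

    Returns ``(burden, differences)``: per-decade heat/cold/net AN and AF
    with pooled eCIs, and the same quantities as changes versus the
    historical-decade average, with difference eCIs computed inside each
    Monte-Carlo draw (GCM-matched) before pooling.
    """
    draws = _draw_coefs(curve, n_sim, seed)
    all_decades = list(historical_decades) + [d for d in decades if d not in historical_decades]
    per_decade_point = {}
    per_decade_draws = {}
    n_days = {}
    for dec in all_decades:
        per_decade_point[dec] = decade_burden(curve, series, D, dec, region, cause)
        per_decade_draws[dec] = _an_draws(curve, series, D, dec, draws)
        n_gcms = per_decade_draws[dec]["heat"].shape[1]
        n_days[dec] = len(_decade_frame(series, dec)) // n_gcms

    burden_rows = []
    for dec in all_decades:
        point = per_decade_point[dec].set_index("component")
        total = D * n_days[dec]
        for c in _COMPONENTS:
            flat = per_decade_draws[dec][c].ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            r = point.loc[c]
            burden_rows.append(
                {
                    "region": r["region"],
                    "cause": r["cause"],
                    "scenario": r["scenario"],
                    "decade": dec,
                    "component": c,
                    "an": r["an"],
                    "af_pct": r["af_pct"],
                    "eci_low": float(lo),
                    "eci_high": float(hi),
                    "af_eci_low": 100.0 * float(lo) / total,
                    "af_eci_high": 100.0 * float(hi) / total,
                }
            )
    burden = pd.DataFrame(burden_rows)

    # Differences vs the historical average, matched within draw and GCM.
    hist_point = pd.concat([per_decade_point[d] for d in historical_decades])
    diff_point = difference_vs_historical(
        burden[~burden["decade"].isin(historical_decades)][
            ["region", "cause", "scenario", "decade", "component", "an", "af_pct"]
        ],
        hist_point,
    )
    diff_rows = []
    for dec in [d for d in all_decades if d not in historical_decades]:
        total = D * n_days[dec]
        for c in _COMPONENTS:
            af_dec = 100.0 * per_decade_draws[dec][c] / total
            af_hist = np.mean(
                [
                    100.0 * per_decade_draws[h][c] / (D * n_days[h])
                    for h in historical_decades
                ],
                axis=0,
            )
            d_af = (af_dec - af_hist).ravel()
            an_hist = np.mean([per_decade_draws[h][c] for h in historical_decades], axis=0)
            d_an = (per_decade_draws[dec][c] - an_hist).ravel()
            lo_af, hi_af = np.percentile(d_af, [2.5, 97.5])
            lo_an, hi_an = np.percentile(d_an, [2.5, 97.5])
            mask = (diff_point["decade"] == dec) & (diff_point["component"] == c)
            diff_rows.append(
                {
                    **diff_point[mask].iloc[0].to_dict(),
                    "d_an_eci_low": float(lo_an),
                    "d_an_eci_high": float(hi_an),
                    "d_af_eci_low": float(lo_af),
                    "d_af_eci_high": float(hi_af),
                }
            )
    return burden, pd.DataFrame(diff_rows)
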