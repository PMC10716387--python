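"""Monthly additive quantile-mapping bias correction.

A climate model's daily temperatures are adjusted so that, month by
month, the distribution of its detrended values matches the detrended
observational distribution over an overlap period, while the model's
own long-term trend passes through unchanged.  Corrections are additive
offsets (observed quantile minus model quantile) on a fixed probability
grid; beyond the outermost grid points the offset is held constant.
Detrending before both fitting and quantile lookup keeps the offset a
function of the weather anomaly rather than of calendar time, which is
what preserves the warming trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrectionFunction", "fit_correction", "apply_correction"]

P_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)  # p = 0.01 .. 0.99


@dataclass(frozen=True)
class CorrectionFunction:
    """Quantile-dependent additive offset for one calendar month.

    ``model_quantiles`` are the detrended model-historical quantiles at
    ``quantile_grid``; a day's detrended value is located on them to find
    its probability, and ``offsets`` (observed minus model quantile, in
    degrees Celsius) is interpolated at that probability.
    """

    calendar_month: int
    quantile_grid: np.ndarray
    offsets: np.ndarray
    model_quantiles: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quantile_grid, dtype=float)
        if not ((q > 0) & (q < 1)).all() or (np.diff(q) <= 0).any():
            raise ValueError("quantile grid must be strictly increasing in (0, 1)")
        if not np.isfinite(self.offsets).all():
            raise ValueError("offsets must be finite")

    def offset_for(self, detrended_values: np.ndarray) -> np.ndarray:
        # model_quantiles may contain ties; np.interp handles them by
        # taking the right-most, which keeps the map monotone.
        p = np.interp(detrended_values, self.model_quantiles, self.quantile_grid)
        return np.interp(p, self.quantile_grid, self.offsets)


def _linear_trend(index: pd.DatetimeIndex, values: np.ndarray):
    """Least-squares linear trend; returns the fitted values."""
    t = (index - index[0]).days.to_numpy(dtype=float)
    t = t - t.mean()
    coef = np.polyfit(t, values, 1)
    return np.polyval(coef, t), coef[0]  # fitted, slope per day


def fit_correction(
    obs: pd.DataFrame,
    model_hist: pd.DataFrame,
    overlap: tuple[str, str] | None = None,
    min_days_per_month: int = 20,
) -> dict[int, CorrectionFunction]:
    """Fit one correction function per calendar month over the overlap.

    Both series are reduced to the overlap period and linearly detrended
    there; offsets are observed minus model empirical quantiles on
    p = 0.01..0.99.  Fewer than ``min_days_per_month`` overlap days in any
    month is rejected.
    """
    o = obs["temp_c"]
    m = model_hist["temp_c"]
    if overlap is not None:
        o = o.loc[overlap[0] : overlap[1]]
        m = m.loc[overlap[0] : overlap[1]]
    common = o.index.intersection(m.index)
    if len(common) == 0:
        raise ValueError("observed and model series do not overlap")
    o = o.loc[common]
    m = m.loc[common]
    o_fit, _ = _linear_trend(o.index, o.to_numpy(dtype=float))
    m_fit, _ = _linear_trend(m.index, m.to_numpy(dtype=float))
    o_anom = o.to_numpy(dtype=float) - o_fit + o.to_numpy(dtype=float).mean()
    m_anom = m.to_numpy(dtype=float) - m_fit + m.to_numpy(dtype=float).mean()
    months = common.month.to_numpy()
    corrections: dict[int, CorrectionFunction] = {}
    for month in range(1, 13):
        mask = months == month
        if mask.sum() < min_days_per_month:
            raise ValueError(
                f"only {int(mask.sum())} overlap days in month {month}; "
                f"need at least {min_days_per_month}"
            )
        oq = np.quantile(o_anom[mask], P_GRID, method="linear")
        mq = np.quantile(m_anom[mask], P_GRID, method="linear")
        corrections[month] = CorrectionFunction(
            calendar_month=month,
            quantile_grid=P_GRID.copy(),
            offsets=oq - mq,
            model_quantiles=mq,
        )
    return corrections


def apply_correction(
    series: pd.DataFrame,
    corrections: dict[int, CorrectionFunction],
    reference_period: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Correct a daily series (which may extend far beyond the fit period).

    The day's long-term local level (its decade's mean) is removed and the
    mean level of the ``reference_period`` (default: the series' first
    thirty years, i.e. the calibration overlap) is added back, which maps
    the day onto the overlap-period climate regardless of how non-linear
    the warming trend is; the day's within-month quantile is located on
    the model climatology there and the offset at that quantile is added
    to the raw value.  Because the level is constant within any
    month-year, the correction is a monotone function of the raw value
    within each month (exact rank preservation), and because the offset
    depends only on the stationary anomaly, the series' trend survives
    correction.
    """
    out = series.copy()
    values = out["temp_c"].to_numpy(dtype=float)
    idx = pd.DatetimeIndex(out.index)
    decade = (idx.year // 10) * 10
    level = pd.Series(values, index=decade).groupby(level=0).transform("mean").to_numpy()
    if reference_period is None:
        ref_mask = idx < idx[0] + pd.DateOffset(years=30)
    else:
        ref_mask = (idx >= pd.Timestamp(reference_period[0])) & (
            idx <= pd.Timestamp(reference_period[1])
        )
        if not ref_mask.any():
            raise ValueError("reference period does not intersect the series")
    ref_level = values[ref_mask].mean()
    anom = values - level + ref_level
    months = idx.month.to_numpy()
    corrected = values.copy()
    for month, corr in corrections.items():
        mask = months == month
        if mask.any():
            corrected[mask] = values[mask] + corr.offset_for(anom[mask])
    out["temp_c"] = corrected
    return out


def corrections_frame(corrections: dict[int, CorrectionFunction]) -> pd.DataFrame:
    """Serialise corrections as tidy rows (month, probability, offset)."""
    rows = []
    for month in sorted(corrections):
        c = corrections[month]
        for p, off in zip(c.quantile_grid, c.offsets):
            rows.append({"month": month, "probability": p, "offset": off})
    return pd.DataFrame(rows)
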