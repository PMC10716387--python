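"""Reduction of the bi-dimensional fit to overall cumulative and
lag-response curves, the minimum-mortality temperature, and relative
risks with delta-method confidence intervals.

Summing the lag basis over the integer lags 0..max_lag collapses the
cross-basis coefficients ``theta`` (exposure-major) onto a reduced
coefficient vector ``eta`` of exposure-basis length; the cumulative log
relative risk between two temperatures is then a contrast in the
exposure basis applied to ``eta``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccfit import FittedModel
from .splines import CrossBasisSpec, SplineSpec, natural_cubic_basis

__all__ = [
    "ReducedCurve",
    "RREstimate",
    "reduce_overall",
    "find_mmt",
    "rr_at",
    "lag_response_at",
    "curve_frame",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RREstimate:
    """Relative risk with a 95% confidence interval at one temperature."""

    temperature: float
    rr: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


@dataclass(frozen=True)
class ReducedCurve:
    """Overall cumulative exposure-response curve with reduced lag dimension.

    ``coef``/``vcov`` parameterise the cumulative log relative risk in the
    exposure spline basis; ``tmm`` (once set) is the reference so that
    RR(tmm) = 1 exactly.  ``display_range`` is the 1st-99th percentile
    span of the observed temperatures, used for reporting grids.
    """

    coef: np.ndarray
    vcov: np.ndarray
    exposure_spec: SplineSpec
    tmm: float | None = None
    mmt_on_boundary: bool = False
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        vcov = np.asarray(self.vcov, dtype=float)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "vcov", (vcov + vcov.T) / 2.0)
        if coef.shape != (self.exposure_spec.ndim,):
            raise ValueError("reduced coefficient length must match the exposure basis")
        if np.linalg.eigvalsh(self.vcov).min() < -1e-8 * max(1.0, np.abs(vcov).max()):
            raise ValueError("reduced covariance is not positive semidefinite")

    def log_rr(self, temps, ref: float | None = None) -> np.ndarray:
        """Cumulative log RR at ``temps`` relative to ``ref`` (default tmm)."""
        if ref is None:
            if self.tmm is None:
                raise ValueError("reference temperature not set; run find_mmt first")
            ref = self.tmm
        contrast = natural_cubic_basis(np.atleast_1d(temps), self.exposure_spec)
        contrast = contrast - natural_cubic_basis(float(ref), self.exposure_spec)
        return contrast @ self.coef

    def log_rr_se(self, temps, ref: float | None = None) -> np.ndarray:
        if ref is None:
            ref = self.tmm
        contrast = natural_cubic_basis(np.atleast_1d(temps), self.exposure_spec)
        contrast = contrast - natural_cubic_basis(float(ref), self.exposure_spec)
        var = np.einsum("ij,jk,ik->i", contrast, self.vcov, contrast)
        return np.sqrt(np.maximum(var, 0.0))


def reduce_overall(model: FittedModel, spec: CrossBasisSpec) -> ReducedCurve:
    """Collapse the lag dimension by summing the lag basis over lags 0..max_lag.

    With exposure-major coefficients ``theta[i, j]`` and lag-basis sums
    ``s[j] = sum_l B_lag_j(l)``, the reduced coefficients are
    ``eta[i] = sum_j theta[i, j] * s[j]``; the covariance maps through the
    same linear transform.
    """
    if not model.converged or model.coef is None:
        raise ValueError("model did not converge; no reduction available")
    de, dl = spec.n_exposure, spec.n_lag
    theta = model.crossbasis_coef()
    if theta.shape != (de * dl,):
        raise ValueError(
            f"cross-basis block has {theta.shape[0]} coefficients, expected {de * dl}"
        )
    s = spec.lag_basis().sum(axis=0)  # (dl,)
    A = np.kron(np.eye(de), s)  # (de, de*dl), exposure-major layout
    eta = A @ theta
    V = A @ model.crossbasis_vcov() @ A.T
    return ReducedCurve(coef=eta, vcov=V, exposure_spec=spec.exposure_spec)


def find_mmt(
    curve: ReducedCurve,
    temps,
    search_percentiles: tuple[float, float] = (1.0, 99.0),
    grid_step: float = 0.1,
) -> ReducedCurve:
    """Locate the minimum-mortality temperature on a fixed grid.

    The cumulative log RR is minimised on a ``grid_step``-spaced grid over
    the ``search_percentiles`` span of the observed temperature
    distribution; exact ties break toward the median temperature.  A
    minimum at either end of the grid is flagged as a boundary solution.
    Returns a new curve with ``tmm`` and ``display_range`` set.
    """
    arr = np.asarray(temps, dtype=float)
    lo, hi = np.percentile(arr, search_percentiles)
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    ref = float(np.median(arr))
    values = curve.log_rr(grid, ref=ref)
    if not np.isfinite(values).all():
        raise ValueError("curve evaluates to non-finite values on the search grid")
    vmin = values.min()
    ties = np.flatnonzero(values <= vmin + 1e-12)
    best = ties[np.argmin(np.abs(grid[ties] - ref))]
    return dataclasses.replace(
        curve,
        tmm=float(grid[best]),
        mmt_on_boundary=bool(best == 0 or best == len(grid) - 1),
        display_range=(float(lo), float(hi)),
    )


def rr_at(curve: ReducedCurve, temperature: float) -> RREstimate:
    """Cumulative RR (and 95% CI) at one temperature versus the MMT.

    Temperatures beyond the spline boundary knots are evaluated through
    the natural linear continuation and flagged ``extrapolated``.
    """
    if curve.tmm is None:
        raise ValueError("reference temperature not set; run find_mmt first")
    t = float(temperature)
    logrr = float(curve.log_rr([t])[0])
    se = float(curve.log_rr_se([t])[0])
    lo, hi = curve.exposure_spec.boundary_knots
    return RREstimate(
        temperature=t,
        rr=float(np.exp(logrr)),
        ci_low=float(np.exp(logrr - Z95 * se)),
        ci_high=float(np.exp(logrr + Z95 * se)),
        extrapolated=bool(t < lo or t > hi),
    )


def lag_response_at(
    model: FittedModel,
    spec: CrossBasisSpec,
    temperature: float,
    tmm: float,
) -> pd.DataFrame:
    """Lag-specific RRs at ``temperature`` versus ``tmm`` for lags 0..max_lag.

    The lag-l contrast is the Kronecker product of the exposure contrast
    with the lag basis evaluated at l; CIs are delta-method on the
    cross-basis coefficient block.  The product of the lag-specific RRs
    equals the overall cumulative RR.
    """
    if not model.converged or model.coef is None:
        raise ValueError("model did not converge")
    theta = model.crossbasis_coef()
    V = model.crossbasis_vcov()
    d_exp = natural_cubic_basis(float(temperature), spec.exposure_spec) - natural_cubic_basis(
        float(tmm), spec.exposure_spec
    )
    B_lag = spec.lag_basis()
    rows = []
    for lag in range(spec.max_lag + 1):
        c = np.kron(d_exp, B_lag[lag])
        logrr = float(c @ theta)
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        rows.append(
            {
                "lag": lag,
                "rr": np.exp(logrr),
                "ci_low": np.exp(logrr - Z95 * se),
                "ci_high": np.exp(logrr + Z95 * se),
            }
        )
    return pd.DataFrame(rows)


def curve_frame(curve: ReducedCurve, n_points: int = 100) -> pd.DataFrame:
    """Tabulate (temperature, rr, ci_low, ci_high) over the display range."""
    if curve.display_range is None or curve.tmm is None:
        raise ValueError("curve has no display range; run find_mmt first")
    grid = np.linspace(*curve.display_range, n_points)
    logrr = curve.log_rr(grid)
    se = curve.log_rr_se(grid)
    return pd.DataFrame(
        {
            "temperature": grid,
            "rr": np.exp(logrr),
            "ci_low": np.exp(logrr - Z95 * se),
            "ci_high": np.exp(logrr + Z95 * se),
        }
    )
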