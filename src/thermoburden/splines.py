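"""Natural cubic spline bases and the exposure-lag cross-basis.

The exposure-response and lag-response dimensions of a distributed lag
non-linear model (DLNM) are each represented with a natural (restricted)
cubic spline: cubic between the boundary knots, with zero second
derivative at the boundaries, and continued linearly beyond them.  The
cross-basis is the tensor product of the two bases accumulated over the
lag window, so that row ``t`` of the cross-basis matrix depends only on
the exposures on days ``t, t-1, ..., t-max_lag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "natural_cubic_basis",
    "lag_knots_log",
    "build_crossbasis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for one natural cubic spline basis.

    Parameters
    ----------
    internal_knots
        Strictly increasing knots, strictly inside the boundary knots.
        May be empty, in which case the basis (without intercept) is a
        single column affine in ``x``.
    boundary_knots
        Pair ``(low, high)``; the spline is linear beyond these.
    with_intercept
        If True the basis spans constants; dimension is
        ``len(internal_knots) + 2``, otherwise ``+ 1``.
    """

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    with_intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.internal_knots)
        lo, hi = (float(b) for b in self.boundary_knots)
        object.__setattr__(self, "internal_knots", ik)
        object.__setattr__(self, "boundary_knots", (lo, hi))
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"boundary knots must satisfy low < high, got {(lo, hi)}")
        if any(not lo < k < hi for k in ik):
            raise ValueError("internal knots must lie strictly inside the boundary knots")
        if any(a >= b for a, b in zip(ik, ik[1:])):
            raise ValueError("internal knots must be strictly increasing")

    @property
    def ndim(self) -> int:
        return len(self.internal_knots) + 1 + int(self.with_intercept)

    @classmethod
    def from_percentiles(
        cls,
        x: Sequence[float],
        probs: Sequence[float],
        boundary: tuple[float, float] | None = None,
        with_intercept: bool = False,
    ) -> "SplineSpec":
        """Place internal knots at percentiles of ``x`` (linear interpolation
        between order statistics); boundary knots default to the data range."""
        arr = np.asarray(x, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("x contains non-finite values")
        knots = np.quantile(arr, np.asarray(probs, dtype=float) / 100.0, method="linear")
        if boundary is None:
            boundary = (float(arr.min()), float(arr.max()))
        return cls(tuple(knots), boundary, with_intercept)

    @classmethod
    def from_df(cls, x: Sequence[float], df: int, with_intercept: bool = False) -> "SplineSpec":
        """Knots at equally spaced percentiles giving ``df`` basis columns."""
        n_internal = df - 1 - int(with_intercept)
        if n_internal < 0:
            raise ValueError(f"df={df} too small for this basis")
        probs = 100.0 * np.arange(1, n_internal + 1) / (n_internal + 1)
        return cls.from_percentiles(x, probs, with_intercept=with_intercept)

    def to_dict(self) -> dict:
        return {
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "with_intercept": self.with_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(tuple(d["internal_knots"]), tuple(d["boundary_knots"]), d["with_intercept"])


def _ns_transform(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Augmented knot vector and the projection enforcing naturalness.

    The unconstrained cubic B-spline basis on the augmented knots has
    ``len(internal) + 4`` columns.  Requiring zero second derivative at
    both boundary knots removes two dimensions; the projection onto the
    orthogonal complement of the constraint rows (via QR) yields the
    natural basis.  Dropping the first B-spline column first removes the
    constant so the basis has no intercept.
    """
    lo, hi = spec.boundary_knots
    t = np.array([lo] * 4 + list(spec.internal_knots) + [hi] * 4, dtype=float)
    m = len(t) - 4
    # Second derivatives of every B-spline column at the two boundaries.
    d2 = BSpline(t, np.eye(m), 3).derivative(2)(np.array([lo, hi]))  # (2, m)
    keep = slice(None) if spec.with_intercept else slice(1, None)
    const = d2[:, keep]
    q, _ = np.linalg.qr(const.T, mode="complete")
    proj = q[:, 2:]  # orthonormal basis of the null space of the constraints
    return t, (np.eye(m)[:, keep] @ proj)


def natural_cubic_basis(x: Sequence[float], spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Beyond the boundary knots the basis is continued linearly (first-order
    Taylor expansion about the nearer boundary), which is exact for a
    natural spline.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    lo, hi = spec.boundary_knots
    t, proj = _ns_transform(spec)
    m = proj.shape[0]

    out = np.empty((x.size, m))
    inside = (x >= lo) & (x <= hi)
    if inside.any():
        out[inside] = BSpline.design_matrix(x[inside], t, 3).toarray()
    spl = BSpline(t, np.eye(m), 3)
    dspl = spl.derivative(1)
    for mask, b in (((x < lo), lo), ((x > hi), hi)):
        if mask.any():
            out[mask] = spl(b) + (x[mask] - b)[:, None] * dspl(b)

    basis = out @ proj
    return basis[0] if scalar else basis


def lag_knots_log(max_lag: float, n_knots: int) -> np.ndarray:
    """Knots at equal intervals on the log-lag scale, strictly between
    lag 1 and ``max_lag`` (lag 0 is excluded from the log grid)."""
    if max_lag < 1 or n_knots < 1:
        raise ValueError("max_lag and n_knots must be >= 1")
    grid = np.linspace(0.0, np.log(max_lag), n_knots + 2)
    return np.exp(grid[1:-1])


@dataclass(frozen=True)
class CrossBasisSpec:
    """Bi-dimensional exposure x lag basis specification.

    The exposure basis carries no intercept so the cumulative effect at
    the reference temperature is identically zero; the lag basis carries
    an intercept so lag-0 effects remain representable.
    """

    exposure_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = 14

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.exposure_spec.with_intercept:
            raise ValueError("exposure basis must not include an intercept")
        if not self.lag_spec.with_intercept:
            raise ValueError("lag basis must include an intercept")

    @property
    def n_exposure(self) -> int:
        return self.exposure_spec.ndim

    @property
    def n_lag(self) -> int:
        return self.lag_spec.ndim

    @property
    def ncol(self) -> int:
        return self.n_exposure * self.n_lag

    def lag_basis(self) -> np.ndarray:
        """Lag basis evaluated on the integer lags 0..max_lag."""
        return natural_cubic_basis(np.arange(self.max_lag + 1, dtype=float), self.lag_spec)

    @classmethod
    def default(
        cls,
        temps: Sequence[float],
        exposure_percentiles: Sequence[float] = (10.0, 75.0, 90.0),
        n_lag_knots: int = 3,
        max_lag: int = 14,
    ) -> "CrossBasisSpec":
        """Exposure knots at percentiles of the observed temperature
        distribution (default 10th/75th/90th), boundary at its range;
        lag knots at equal log intervals up to ``max_lag``."""
        exp_spec = SplineSpec.from_percentiles(temps, exposure_percentiles)
        lag_spec = SplineSpec(
            tuple(lag_knots_log(max_lag, n_lag_knots)), (0.0, float(max_lag)), with_intercept=True
        )
        return cls(exp_spec, lag_spec, max_lag)

    def to_dict(self) -> dict:
        return {
            "exposure_spec": self.exposure_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            SplineSpec.from_dict(d["exposure_spec"]),
            SplineSpec.from_dict(d["lag_spec"]),
            d["max_lag"],
        )


@dataclass
class CrossBasisMatrix:
    """Cross-basis design block for one exposure series.

    ``matrix`` has one row per day of the input series; rows without a
    complete ``max_lag``-day history (``valid`` False) are NaN.  Columns
    are exposure-major: column ``i * n_lag + j`` pairs exposure basis
    function ``i`` with lag basis function ``j``.
    """

    matrix: np.ndarray
    valid: np.ndarray
    spec: CrossBasisSpec
    temps: np.ndarray = field(repr=False)


def build_crossbasis(temps: Sequence[float], spec: CrossBasisSpec) -> CrossBasisMatrix:
    """Accumulate the exposure x lag tensor over the lag window.

    Row ``t``, column ``(i, j)`` equals
    ``sum_l B_exp_i(T[t-l]) * B_lag_j(l)`` for ``l = 0..max_lag``.
    """
    temps = np.asarray(temps, dtype=float)
    L = spec.max_lag
    if temps.size <= L:
        raise ValueError(f"series of length {temps.size} shorter than max_lag+1={L + 1}")
    E = natural_cubic_basis(temps, spec.exposure_spec)  # (n, de)
    B_lag = spec.lag_basis()  # (L+1, dl)
    n, de = E.shape
    dl = B_lag.shape[1]
    X = np.zeros((n, de, dl))
    for lag in range(L + 1):
        X[L:] += E[L - lag : n - lag, :, None] * B_lag[lag][None, None, :]
    X = X.reshape(n, de * dl)
    valid = np.zeros(n, dtype=bool)
    valid[L:] = True
    X[~valid] = np.nan
    return CrossBasisMatrix(matrix=X, valid=valid, spec=spec, temps=temps)
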