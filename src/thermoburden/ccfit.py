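"""Time-stratified case-crossover strata and the conditional-logistic fit.

Each death defines its own stratum: the case day plus every other day in
the same calendar month and year that shares the case day's day-of-week
(3 or 4 controls).  Conditioning on one event per stratum reduces the
stratum's likelihood contribution to a softmax over its candidate days,
which is maximised by Newton-Raphson with step-halving.  Deaths sharing
a case date have identical strata, so the likelihood is evaluated on
unique case dates with multiplicity weights -- algebraically identical to
the per-death sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import CrossBasisMatrix, SplineSpec, natural_cubic_basis

__all__ = [
    "Stratum",
    "DesignMatrix",
    "FittedModel",
    "NonIdentifiedError",
    "build_strata",
    "build_design",
    "fit_conditional_logistic",
]


class NonIdentifiedError(RuntimeError):
    """Raised when the partial likelihood has a flat or unbounded direction."""


@dataclass(frozen=True)
class Stratum:
    """One case day with its time-stratified referent (control) days."""

    case_day: pd.Timestamp
    control_days: tuple[pd.Timestamp, ...]

    def __post_init__(self) -> None:
        if self.case_day in self.control_days:
            raise ValueError("case day must not appear among the controls")


def referent_days(day: pd.Timestamp) -> list[pd.Timestamp]:
    """All other same-weekday days in the same month and year."""
    day = pd.Timestamp(day)
    month_days = pd.date_range(day.replace(day=1), day.replace(day=day.days_in_month), freq="D")
    return [d for d in month_days if d.dayofweek == day.dayofweek and d != day]


def build_strata(
    death_dates,
    available_days: pd.DatetimeIndex | None = None,
) -> tuple[list[Stratum], int]:
    """One stratum per death (time-stratified referents).

    ``available_days`` restricts the design to days with a usable design
    row (complete lag history, weather present): control days outside it
    are dropped, and a stratum whose case day is unusable or that retains
    no control is dropped entirely.  Returns ``(strata, n_dropped)``.
    """
    avail = None if available_days is None else pd.DatetimeIndex(available_days)
    strata: list[Stratum] = []
    dropped = 0
    cache: dict[pd.Timestamp, Stratum | None] = {}
    for raw in death_dates:
        day = pd.Timestamp(raw)
        if day not in cache:
            controls = referent_days(day)
            if avail is not None:
                if day not in avail:
                    cache[day] = None
                else:
                    controls = [c for c in controls if c in avail]
                    cache[day] = Stratum(day, tuple(controls)) if controls else None
            else:
                cache[day] = Stratum(day, tuple(controls))
        st = cache[day]
        if st is None:
            dropped += 1
        else:
            strata.append(st)
    return strata, dropped


@dataclass
class DesignMatrix:
    """Day-indexed covariate rows: cross-basis block, holiday, humidity spline.

    Column layout is fixed: the cross-basis block first (``n_crossbasis``
    columns), then the holiday indicator, then the humidity natural-spline
    block.
    """

    X: np.ndarray
    dates: pd.DatetimeIndex
    valid: np.ndarray
    n_crossbasis: int
    columns: list[str] = field(default_factory=list)

    @property
    def usable_days(self) -> pd.DatetimeIndex:
        return self.dates[self.valid]

    def rows_for(self, days) -> np.ndarray:
        idx = self.dates.get_indexer(pd.DatetimeIndex(days))
        if (idx < 0).any():
            missing = pd.DatetimeIndex(days)[idx < 0]
            raise KeyError(f"no design rows for {list(missing[:3])}...")
        return self.X[idx]

    @property
    def crossbasis_slice(self) -> slice:
        return slice(0, self.n_crossbasis)


def build_design(
    weather: pd.DataFrame,
    crossbasis: CrossBasisMatrix,
    humidity_df: int = 3,
) -> DesignMatrix:
    """Assemble per-day covariate rows from weather and the cross-basis."""
    if len(weather) != crossbasis.matrix.shape[0]:
        raise ValueError("weather and cross-basis cover different numbers of days")
    rh = weather["rh_pct"].to_numpy(dtype=float)
    rh_spec = SplineSpec.from_df(rh, humidity_df)
    H = natural_cubic_basis(rh, rh_spec)
    holiday = weather["holiday"].to_numpy(dtype=float)[:, None]
    X = np.hstack([np.nan_to_num(crossbasis.matrix, nan=0.0), holiday, H])
    X[~crossbasis.valid] = np.nan
    k = crossbasis.matrix.shape[1]
    cols = (
        [f"cb{i}" for i in range(k)]
        + ["holiday"]
        + [f"rh{j}" for j in range(H.shape[1])]
    )
    return DesignMatrix(
        X=X,
        dates=pd.DatetimeIndex(weather.index),
        valid=crossbasis.valid.copy(),
        n_crossbasis=k,
        columns=cols,
    )


@dataclass
class FittedModel:
    """Conditional-logistic estimate: coefficients, covariance, diagnostics."""

    coef: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    n_strata: int
    n_dropped: int = 0
    n_iter: int = 0
    message: str = ""
    columns: list[str] = field(default_factory=list)
    n_crossbasis: int = 0

    def crossbasis_coef(self) -> np.ndarray:
        return self.coef[: self.n_crossbasis]

    def crossbasis_vcov(self) -> np.ndarray:
        return self.vcov[: self.n_crossbasis, : self.n_crossbasis]


def _stack_strata(strata: list[Stratum], design: DesignMatrix):
    """Collapse per-death strata onto unique case days with weights."""
    counts: dict[pd.Timestamp, int] = {}
    reps: dict[pd.Timestamp, Stratum] = {}
    for st in strata:
        counts[st.case_day] = counts.get(st.case_day, 0) + 1
        reps[st.case_day] = st
    rows = []
    stratum_sizes = []
    weights = []
    for day, st in reps.items():
        days = [st.case_day, *st.control_days]
        rows.append(design.rows_for(days))
        stratum_sizes.append(len(days))
        weights.append(float(counts[day]))
    X = np.vstack(rows)
    if np.isnan(X).any():
        raise ValueError("design rows with incomplete lag history entered the likelihood")
    sizes = np.asarray(stratum_sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    case_rows = starts  # first row of each stratum is the case day
    return X, starts, sizes, case_rows, np.asarray(weights)


def _loglik_parts(theta, X, starts, sizes, case_rows, w):
    eta = X @ theta
    S = len(starts)
    # per-stratum log-sum-exp and softmax probabilities
    maxs = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - np.repeat(maxs, sizes))
    denom = np.add.reduceat(z, starts)
    lse = maxs + np.log(denom)
    p = z / np.repeat(denom, sizes)
    ll = float(np.sum(w * (eta[case_rows] - lse)))
    case_ind = np.zeros(len(eta))
    case_ind[case_rows] = 1.0
    w_row = np.repeat(w, sizes)
    grad = X.T @ (w_row * (case_ind - p))
    # Hessian of ll: -(X' diag(p w) X - sum_s w_s mu_s mu_s')
    M = np.empty((S, X.shape[1]))
    pw = p * w_row
    pX = p[:, None] * X
    np.add.reduceat(pX, starts, axis=0, out=M)
    H = -(X.T @ (pw[:, None] * X) - (M * w[:, None]).T @ M)
    return ll, grad, H


def fit_conditional_logistic(
    strata: list[Stratum],
    design: DesignMatrix,
    max_iter: int = 50,
    ll_tol: float = 1e-9,
    grad_tol: float = 1e-6,
    n_dropped: int = 0,
) -> FittedModel:
    """Maximise the stratified partial likelihood by damped Newton-Raphson.

    Starts at zero; a step is halved until it does not decrease the
    log-likelihood; convergence requires both a relative log-likelihood
    change below ``ll_tol`` and a maximum absolute gradient below
    ``grad_tol``.  The covariance is the inverse observed information at
    the optimum.  Flat likelihood directions (e.g. a covariate constant
    within every stratum) raise :class:`NonIdentifiedError`; an unbounded
    likelihood (perfect separation) is reported via ``converged=False``
    with coefficients withheld.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    X, starts, sizes, case_rows, w = _stack_strata(strata, design)
    p = X.shape[1]
    theta = np.zeros(p)
    ll, grad, H = _loglik_parts(theta, X, starts, sizes, case_rows, w)

    # Identifiability: directions with no within-stratum variation leave
    # the likelihood flat; detect them from the information matrix at zero.
    info = -H
    eig = np.linalg.eigvalsh(info)
    scale = max(eig.max(), 1.0)
    if eig.min() < 1e-10 * scale:
        flat = np.linalg.eigh(info)[1][:, 0]
        raise NonIdentifiedError(
            "partial likelihood is flat along direction "
            f"{np.array2string(flat, precision=3)}; "
            "a covariate may be constant within every stratum"
        )
    eig0_min = eig.min()

    n_iter = 0
    converged = False
    message = ""
    # likelihood comparisons are only meaningful above floating noise
    ll_noise = 64.0 * np.finfo(float).eps * (1.0 + abs(ll))
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        step_ok = False
        for _ in range(30):
            cand = theta + step
            ll_new, grad_new, H_new = _loglik_parts(cand, X, starts, sizes, case_rows, w)
            if ll_new >= ll - ll_noise:
                step_ok = True
                break
            step = step / 2.0
        if not step_ok:
            message = "step-halving failed to improve the likelihood"
            break
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-12)
        theta, ll, grad, H = cand, ll_new, grad_new, H_new
        ll_noise = 64.0 * np.finfo(float).eps * (1.0 + abs(ll))
        if rel_change < ll_tol and np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
    else:
        message = f"no convergence in {max_iter} iterations"

    if not converged:
        if not message:
            message = "optimization stalled before the gradient vanished"
        return FittedModel(
            coef=None,
            vcov=None,
            loglik=ll,
            converged=False,
            n_strata=len(strata),
            n_dropped=n_dropped,
            n_iter=n_iter,
            message=message + " (estimates withheld; likelihood may be unbounded)",
            columns=design.columns,
            n_crossbasis=design.n_crossbasis,
        )

    # a separable design drives the information to zero along the
    # separating direction as the softmax saturates
    eig_opt = np.linalg.eigvalsh(-H)
    if eig_opt.min() < 1e-3 * eig0_min:
        return FittedModel(
            coef=None,
            vcov=None,
            loglik=ll,
            converged=False,
            n_strata=len(strata),
            n_dropped=n_dropped,
            n_iter=n_iter,
            message=(
                "information matrix is singular at the optimum (separable or "
                "degenerate design); estimates non-identified and withheld"
            ),
            columns=design.columns,
            n_crossbasis=design.n_crossbasis,
        )

    vcov = np.linalg.inv(-H)
    vcov = (vcov + vcov.T) / 2.0
    return FittedModel(
        coef=theta,
        vcov=vcov,
        loglik=ll,
        converged=True,
        n_strata=len(strata),
        n_dropped=n_dropped,
        n_iter=n_iter,
        columns=design.columns,
        n_crossbasis=design.n_crossbasis,
    )


def conditional_loglik(theta, strata: list[Stratum], design: DesignMatrix):
    """Log-likelihood and gradient at an arbitrary parameter vector."""
    X, starts, sizes, case_rows, w = _stack_strata(strata, design)
    ll, grad, _ = _loglik_parts(np.asarray(theta, dtype=float), X, starts, sizes, case_rows, w)
    return ll, grad


def wald_block_test(model: FittedModel, block: slice) -> tuple[float, int, float]:
    """Wald chi-square test that a coefficient block is zero.

    Returns ``(statistic, df, p_value)``.
    """
    from scipy import stats

    b = model.coef[block]
    V = model.vcov[block, block]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(b)
    return stat, df, float(stats.chi2.sf(stat, df))


def aic(model: FittedModel) -> float:
    """Akaike information criterion of the partial likelihood fit."""
    return 2.0 * len(model.coef) - 2.0 * model.loglik
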