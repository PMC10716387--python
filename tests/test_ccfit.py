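"""Time-stratified strata and the conditional-logistic partial likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from thermoburden import ccfit, splines, synth
from thermoburden.ccfit import (
    DesignMatrix,
    NonIdentifiedError,
    Stratum,
    build_design,
    build_strata,
    conditional_loglik,
    fit_conditional_logistic,
    referent_days,
    wald_block_test,
)


def toy_design(dates: pd.DatetimeIndex, X: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        X=np.asarray(X, dtype=float),
        dates=dates,
        valid=np.ones(len(dates), dtype=bool),
        n_crossbasis=X.shape[1],
        columns=[f"x{i}" for i in range(X.shape[1])],
    )


def brute_loglik(theta, stratum_rows):
    """Naive softmax enumeration: case row is first in each stratum."""
    ll = 0.0
    for X in stratum_rows:
        scores = [float(np.dot(x, theta)) for x in X]
        ll += scores[0] - math.log(sum(math.exp(s) for s in scores))
    return ll


def brute_gradient(theta, stratum_rows):
    g = np.zeros(len(theta))
    for X in stratum_rows:
        scores = np.array([float(np.dot(x, theta)) for x in X])
        p = np.exp(scores - scores.max())
        p = p / p.sum()
        g += X[0] - p @ X
    return g


class TestStrata:
    def test_referents_share_weekday_month_year(self):
        """Death on the third Wednesday of a month: controls are exactly
        the other Wednesdays of that month."""
        case = pd.Timestamp("2015-06-17")  # 3rd Wednesday of June 2015
        controls = referent_days(case)
        assert controls == [pd.Timestamp(d) for d in ("2015-06-03", "2015-06-10", "2015-06-24")]
        assert all(d.dayofweek == case.dayofweek for d in controls)

    def test_one_stratum_per_death(self):
        dates = pd.date_range("2016-03-01", periods=100, freq="D")
        strata, dropped = build_strata(dates)
        assert len(strata) == 100 and dropped == 0

    def test_every_stratum_has_3_or_4_controls(self):
        """Exhaustive over all month x weekday combinations, 2013-2019."""
        days = pd.date_range("2013-01-01", "2019-12-31", freq="D")
        sizes = {len(referent_days(d)) for d in days}
        assert sizes == {3, 4}

    def test_strata_without_usable_days_dropped_and_counted(self):
        avail = pd.date_range("2015-06-10", "2015-07-31", freq="D")
        strata, dropped = build_strata(
            ["2015-06-03", "2015-06-17", "2015-07-15"], available_days=avail
        )
        assert dropped == 1  # June 3rd itself unavailable
        assert len(strata) == 2
        june = next(s for s in strata if s.case_day == pd.Timestamp("2015-06-17"))
        assert pd.Timestamp("2015-06-03") not in june.control_days

    def test_case_day_never_among_controls(self):
        with pytest.raises(ValueError):
            Stratum(pd.Timestamp("2015-06-17"), (pd.Timestamp("2015-06-17"),))


class TestLikelihoodOracle:
    """Brute-force softmax enumeration on <= 5-strata toy problems."""

    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(42)
        # Thursdays of January 2015 give a real 5-day stratum calendar
        days = pd.DatetimeIndex(
            ["2015-01-01", "2015-01-08", "2015-01-15", "2015-01-22", "2015-01-29"]
        )
        X = rng.normal(size=(5, 2))
        design = toy_design(days, X)
        strata = []
        rows = []
        for i in range(5):
            controls = tuple(d for j, d in enumerate(days) if j != i)
            strata.append(Stratum(days[i], controls))
            rows.append(np.vstack([X[i], np.delete(X, i, axis=0)]))
        return strata, design, rows

    def test_loglik_and_gradient_match_enumeration(self, toy):
        strata, design, rows = toy
        rng = np.random.default_rng(1)
        for _ in range(5):
            theta = rng.normal(scale=1.5, size=2)
            ll, grad = conditional_loglik(theta, strata, design)
            assert abs(ll - brute_loglik(theta, rows)) < 1e-10
            np.testing.assert_allclose(grad, brute_gradient(theta, rows), atol=1e-10)

    def test_mle_matches_oracle_optimizer(self, toy):
        strata, design, rows = toy
        model = fit_conditional_logistic(strata, design)
        assert model.converged
        res = optimize.minimize(
            lambda th: -brute_loglik(th, rows),
            np.zeros(2),
            jac=lambda th: -brute_gradient(th, rows),
            method="BFGS",
            options={"gtol": 1e-10},
        )
        np.testing.assert_allclose(model.coef, res.x, atol=1e-6)

    def test_matches_statsmodels_conditional_logit(self, toy):
        """Independent implementation cross-check."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        strata, design, rows = toy
        model = fit_conditional_logistic(strata, design)
        X = np.vstack(rows)
        y = np.concatenate([[1, 0, 0, 0, 0] for _ in rows])
        groups = np.repeat(np.arange(5), 5)
        res = ConditionalLogit(y, X, groups=groups).fit(method="newton", disp=0)
        np.testing.assert_allclose(model.coef, res.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(model.vcov)), res.bse, rtol=1e-4)


class TestDegenerateDesigns:
    DAYS = pd.DatetimeIndex(["2015-01-01", "2015-01-08", "2015-01-15", "2015-01-22"])

    def test_single_informative_stratum_is_non_identified(self):
        """With one stratum and a non-zero covariate contrast the partial
        likelihood is unbounded; estimates are withheld."""
        X = np.array([[1.0], [0.0], [0.0], [0.0]])
        design = toy_design(self.DAYS, X)
        strata = [Stratum(self.DAYS[0], tuple(self.DAYS[1:]))]
        model = fit_conditional_logistic(strata, design)
        assert not model.converged
        assert model.coef is None and model.vcov is None
        assert "non-identified" in model.message or "unbounded" in model.message

    def test_two_opposing_strata_give_zero(self):
        """Symmetric contrasts of equal magnitude cancel: theta-hat = 0."""
        X = np.array([[1.0], [0.0], [0.0], [1.0]])
        design = toy_design(self.DAYS, X)
        strata = [
            Stratum(self.DAYS[0], (self.DAYS[1],)),
            Stratum(self.DAYS[2], (self.DAYS[3],)),
        ]
        model = fit_conditional_logistic(strata, design)
        assert model.converged
        np.testing.assert_allclose(model.coef, [0.0], atol=1e-8)

    def test_within_stratum_constant_column_flagged(self):
        """A covariate constant inside every stratum leaves the likelihood
        flat along it."""
        X = np.column_stack([np.random.default_rng(0).normal(size=4), np.ones(4)])
        design = toy_design(self.DAYS, X)
        strata = [
            Stratum(self.DAYS[0], (self.DAYS[1],)),
            Stratum(self.DAYS[3], (self.DAYS[2],)),
        ]
        with pytest.raises(NonIdentifiedError, match="flat"):
            fit_conditional_logistic(strata, design)


class TestFitProperties:
    @pytest.fixture()
    def fitted(self, small_world):
        return small_world

    def test_likelihood_invariant_to_within_stratum_shift(self, fitted):
        """Adding a constant to a covariate within one whole stratum does
        not change the conditional likelihood."""
        deaths = fitted.deaths["date"].iloc[:200]
        strata, _ = build_strata(deaths, fitted.design.usable_days)
        theta = np.full(fitted.design.X.shape[1], 0.05)
        ll0, _ = conditional_loglik(theta, strata, fitted.design)
        shifted = fitted.design
        target = strata[0]
        days = [target.case_day, *target.control_days]
        X2 = shifted.X.copy()
        idx = shifted.dates.get_indexer(pd.DatetimeIndex(days))
        X2[idx, 0] += 7.5
        design2 = DesignMatrix(
            X=X2,
            dates=shifted.dates,
            valid=shifted.valid,
            n_crossbasis=shifted.n_crossbasis,
            columns=shifted.columns,
        )
        # only strata disjoint from the shifted days are guaranteed
        # invariant; stratum 0 shares no days with itself shifted wholesale
        ll1, _ = conditional_loglik(theta, strata, design2)
        # the shifted stratum contributes identically: x_case - x_j unchanged
        other = [s for s in strata if set([s.case_day, *s.control_days]).isdisjoint(days)]
        assert len(other) < len(strata)
        np.testing.assert_allclose(ll1, ll0, atol=1e-8)

    def test_vcov_matches_finite_difference_hessian(self, fitted):
        """Observed-information covariance agrees with a numerical Hessian
        of the partial likelihood at the optimum."""
        model = fitted.model
        deaths = fitted.deaths["date"]
        strata, _ = build_strata(deaths, fitted.design.usable_days)
        k = len(model.coef)
        h = 1e-5
        H = np.zeros((k, k))
        base_grad = conditional_loglik(model.coef, strata, fitted.design)[1]
        for j in range(k):
            step = np.zeros(k)
            step[j] = h
            gp = conditional_loglik(model.coef + step, strata, fitted.design)[1]
            gm = conditional_loglik(model.coef - step, strata, fitted.design)[1]
            H[:, j] = (gp - gm) / (2 * h)
        H = (H + H.T) / 2.0
        vcov_fd = np.linalg.inv(-H)
        scale = np.abs(model.vcov).max()
        np.testing.assert_allclose(model.vcov, vcov_fd, atol=1e-5 * scale, rtol=1e-4)
        assert np.isfinite(base_grad).all()

    def test_null_data_wald_rejection_rate_nominal(self):
        """Type-I error of the Wald test on the cross-basis block under a
        flat true surface is near the nominal 5% level."""
        reps = 120
        rejections = 0
        flat = synth.TrueSurface(
            lambda t: np.zeros_like(np.asarray(t, dtype=float)),
            np.full(15, 1.0 / 15.0),
            15.0,
        )
        weather = synth.simulate_weather(
            synth.WeatherParams("2014-01-01", "2015-12-31", seed=77)
        )
        temps = weather["temp_c"].to_numpy()
        # small cross-basis keeps the Wald statistic well-calibrated at
        # this sample size
        spec = splines.CrossBasisSpec(
            splines.SplineSpec.from_percentiles(temps, (50.0,)),
            splines.SplineSpec(
                tuple(splines.lag_knots_log(14, 1)), (0.0, 14.0), with_intercept=True
            ),
        )
        design = build_design(weather, splines.build_crossbasis(temps, spec))
        rng = np.random.default_rng(123)
        for _ in range(reps):
            deaths = synth.simulate_deaths(
                weather, flat, baseline_rate=4.0, seed=int(rng.integers(2**31))
            )
            strata, _ = build_strata(deaths["date"], design.usable_days)
            model = fit_conditional_logistic(strata, design)
            _, _, p = wald_block_test(model, slice(0, spec.ncol))
            rejections += p < 0.05
        rate = rejections / reps
        # 3-sigma binomial band around 0.05 with 120 replicates
        assert 0.0 <= rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01
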