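"""KM, log-rank and Cox against hand calculations and reference fits."""

import warnings

import numpy as np
import pytest

from irgp.datatypes import PairIndicatorMatrix, ValidationError
from irgp.survival import (cox_fit, km_estimate, logrank_test,
                           univariate_screen)
from irgp.validation import _null_survival


class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(2.5) == 1.0

    def test_censoring_reduces_risk_set(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.at_risk[-1] == 1
        assert km.survival_at(1.0) == pytest.approx(2 / 3)

    def test_curve_is_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(0)
        t, e = _null_survival(200, rng)
        km = km_estimate(t, e)
        assert (np.diff(km.survival) <= 0).all()
        assert (km.survival >= 0).all() and (km.survival <= 1).all()
        assert km.survival_at(0.0) == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(4)
        ta, ea = _null_survival(80, rng)
        tb = rng.exponential(400, 80)
        eb = (rng.random(80) < 0.6).astype(int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_strong_separation_is_significant(self):
        from irgp import SimulationConfig
        from irgp.simulate import (default_planted_pairs,
                                   simulate_expression, simulate_survival)
        base = SimulationConfig(n_tumor=500, n_normal=2, n_genes=10,
                                immune_fraction=1.0, n_de_genes=0,
                                mu_low=6.0, mu_high=6.0, seed=6)
        cfg = SimulationConfig(n_tumor=500, n_normal=2, n_genes=10,
                               immune_fraction=1.0, n_de_genes=0,
                               mu_low=6.0, mu_high=6.0, seed=6,
                               planted_pairs=default_planted_pairs(
                                   base, 1, beta=2.0))
        _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth)
        mask = truth.indicators.values[0] == 1
        t, e = clin.time.to_numpy(), clin.event.to_numpy()
        _, p = logrank_test(t[mask], e[mask], t[~mask], e[~mask])
        assert p < 0.001

    def test_no_events_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test([1.0, 2.0], [0, 0], [3.0], [0])
        assert p == 1.0


class TestCox:
    def test_matches_lifelines_efron(self, survival_20):
        import pandas as pd
        from lifelines import CoxPHFitter
        X, t, e = survival_20
        fit = cox_fit(X, t, e)
        df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e",
                                fit_options={"precision": 1e-12})
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                   atol=1e-6)

    def test_matches_sksurv_breslow(self, survival_20):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        X, t, e = survival_20
        fit = cox_fit(X, t, e, ties="breslow")
        y = np.array([(bool(ev), tt) for ev, tt in zip(e, t)],
                     dtype=[("e", bool), ("t", float)])
        sk = CoxPHSurvivalAnalysis(ties="breslow", alpha=0.0, tol=1e-12)
        sk.fit(X, y)
        np.testing.assert_allclose(fit.coef, sk.coef_, atol=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        t = rng.exponential(100, 50)  # continuous: no ties
        e = (rng.random(50) < 0.7).astype(int)
        fe = cox_fit(X, t, e)
        fb = cox_fit(X, t, e, ties="breslow")
        np.testing.assert_array_equal(fe.coef, fb.coef)

    def test_recovers_generating_beta_binary_covariate(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (1e-3 * np.exp(1.0 * x)))
        e = np.ones(n, dtype=int)
        fit = cox_fit(x[:, None], t, e)
        assert fit.coef[0] == pytest.approx(1.0, abs=0.15)
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]

    def test_constant_covariate_flagged_infinite_se(self):
        rng = np.random.default_rng(7)
        t, e = _null_survival(30, rng)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(X, t, e)
        assert fit.coef[0] == 0.0 and np.isinf(fit.se[0])
        assert np.isfinite(fit.se[1])

    def test_perfect_separation_capped_and_flagged(self):
        # the covariate-1 group all dies first: monotone likelihood
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)]) * 1.0
        e = np.ones(20, dtype=int)
        x = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.warns(UserWarning, match="separation"):
            fit = cox_fit(x[:, None], t, e)
        assert not fit.converged
        assert abs(fit.coef[0]) <= 20.0

    def test_loglik_monotone_under_step_halving(self, survival_20):
        # indirectly: the fitted optimum has (numerically) zero gradient
        from irgp.survival import CoxData, _cox_derivatives
        X, t, e = survival_20
        fit = cox_fit(X, t, e)
        cd = CoxData(t, e)
        _, grad, _ = _cox_derivatives(cd, X[cd.order], fit.coef, "efron")
        assert np.abs(grad).max() < 1e-8


class TestUnivariateScreen:
    def test_planted_pair_retained(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (1e-3 * np.exp(1.0 * x)))
        e = np.ones(n, dtype=int)
        noise = rng.integers(0, 2, size=(5, n))
        pm = PairIndicatorMatrix(
            [(f"A{k}", f"B{k}") for k in range(6)],
            [f"S{j}" for j in range(n)], np.vstack([x, noise]))
        selected, table = univariate_screen(pm, t, e, alpha=0.01)
        assert ("A0", "B0") in selected
        assert table.loc["A0|B0", "p"] < 1e-10

    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(9)
        t, e = _null_survival(100, rng)
        pm = PairIndicatorMatrix([("A", "B")], [f"S{j}" for j in range(100)],
                                 rng.integers(0, 2, (1, 100)))
        selected, _ = univariate_screen(pm, t, e, alpha=0.0)
        assert selected == []
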