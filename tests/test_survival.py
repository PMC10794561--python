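"""Survival-kernel oracles: Cox fits against brute-force partial-likelihood
maximization and an independent library, AUC against exhaustive pair
counting, hand-computed Kaplan-Meier values, and quantile incidence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from conftest import oracle_auc_paircount, oracle_breslow_loglik
from metacvd.survival import (CoxError, CoxPH, SeparationError, auc,
                              fit_cox, km_curve, quantile_incidence)

COX_FIXTURES = [
    # (times, events, x) with n <= 8, single covariate
    ((1, 2, 3, 4, 5, 6), (1, 1, 1, 1, 1, 1), (1, 0, 1, 0, 1, 0)),
    ((2, 2, 4, 5, 7, 8), (1, 0, 1, 1, 0, 1), (0.5, 1.2, -0.3, 0.8, 0.0,
                                              -1.1)),
    ((1, 1, 2, 3), (1, 1, 1, 0), (1, 0, 1, 0)),          # tied event times
    ((3, 1, 4, 1, 5, 9, 2, 6), (1, 0, 1, 1, 0, 1, 1, 0),
     (0.1, -0.2, 0.3, 0.5, -0.5, 0.2, 0.0, 0.4)),
]


class TestCoxOracle:
    @pytest.mark.parametrize("times,events,x", COX_FIXTURES)
    def test_matches_grid_maximization(self, times, events, x):
        """Newton-Raphson equals brute-force maximization of the written-
        out Breslow partial likelihood to 1e-4."""
        times = np.array(times, dtype=float)
        events = np.array(events)
        x = np.array(x, dtype=float)
        fit = fit_cox(times, events, x[:, None], names=["x"])
        grid = np.arange(-5, 5, 1e-4)
        lls = np.array([oracle_breslow_loglik([b], times, events,
                                              x[:, None]) for b in
                        grid[:: 100]])
        # coarse bracket then fine grid around the bracket
        b0 = grid[::100][np.argmax(lls)]
        fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-4)
        lls_fine = np.array([oracle_breslow_loglik([b], times, events,
                                                   x[:, None])
                             for b in fine])
        beta_oracle = fine[np.argmax(lls_fine)]
        assert abs(fit.params[0] - beta_oracle) <= 1e-4 + 1e-4

    def test_two_covariates_matches_optimizer_oracle(self):
        rng = np.random.default_rng(11)
        n = 8
        times = rng.exponential(1, n) + 0.1
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        X = rng.normal(size=(n, 2))
        fit = fit_cox(times, events, X, names=["a", "b"])
        res = optimize.minimize(
            lambda b: -oracle_breslow_loglik(b, times, events, X),
            x0=[0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12})
        assert np.allclose(fit.params, res.x, atol=1e-4)

    def test_matches_statsmodels_breslow(self):
        """Independent cross-check against statsmodels PHReg."""
        from statsmodels.duration.hazard_regression import PHReg
        rng = np.random.default_rng(3)
        n = 300
        X = rng.normal(size=(n, 3))
        lam = 0.1 * np.exp(X @ np.array([0.4, -0.2, 0.0]))
        t = rng.exponential(1 / lam)
        c = rng.exponential(15, n)
        times = np.ceil(np.minimum(t, c) * 10) + 1  # induce ties
        events = (t <= c).astype(int)
        ours = fit_cox(times, events, X, names=list("abc"))
        sm_fit = PHReg(times, X, status=events, ties="breslow").fit()
        assert np.allclose(ours.params, sm_fit.params, atol=1e-6)
        assert np.allclose(ours.bse, sm_fit.bse, atol=1e-6)

    def test_type_one_error_coverage(self):
        """Null covariate: the 95% CI covers 0 in >=93/100 replicates."""
        rng = np.random.default_rng(2024)
        n = 2000
        covered = 0
        for _ in range(100):
            x = rng.standard_normal(n)
            t = rng.exponential(1.0, n)
            c = rng.exponential(2.0, n)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            fit = fit_cox(times, events, x[:, None], names=["x"])
            lo, hi = fit.conf_int[0]
            covered += int(lo <= 0 <= hi)
        assert covered >= 93

    def test_separation_raises(self):
        with pytest.raises(SeparationError, match="x"):
            fit_cox(np.array([1.0, 2.0]), np.array([1, 1]),
                    np.array([[1.0], [0.0]]), names=["x"])

    def test_all_exposed_fail_first_is_separation(self):
        # every x=1 subject fails before any x=0 subject: the partial
        # likelihood is monotone in beta and the MLE is +inf
        with pytest.raises(SeparationError):
            fit_cox(np.arange(1.0, 7.0), np.ones(6, dtype=int),
                    np.array([1.0, 1, 1, 0, 0, 0])[:, None], names=["x"])

    def test_constant_covariate_rejected(self):
        with pytest.raises(CoxError, match="constant covariate: c"):
            fit_cox(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]),
                    np.array([[1.0], [1.0], [1.0]]), names=["c"])

    def test_no_events_rejected(self):
        with pytest.raises(CoxError, match="at least one event"):
            fit_cox(np.array([1.0, 2.0]), np.array([0, 0]),
                    np.array([[1.0], [0.0]]))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(CoxError, match="positive"):
            fit_cox(np.array([0.0, 2.0]), np.array([1, 1]),
                    np.array([[1.0], [0.0]]))

    def test_baseline_hazard_no_censoring(self):
        # with no covariate effect, 1 - exp(-H0) tracks empirical risk
        rng = np.random.default_rng(9)
        n = 4000
        times = rng.exponential(10, n) + 0.01
        events = np.ones(n, dtype=int)
        x = rng.standard_normal(n) * 1e-8  # null covariate
        fit = fit_cox(times, events, x[:, None], names=["x"])
        t_star = float(np.median(times))
        risk = fit.predict_risk(np.zeros((1, 1)), t_star)[0]
        assert abs(risk - (times <= t_star).mean()) < 0.02


class TestAuc:
    def test_forced_example(self):
        res = auc([2, 3, 1, 2.5], [1, 1, 0, 0])
        assert res.auc == 0.75

    def test_perfect_separation(self):
        res = auc([10, 11, 1, 2], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = auc(scores, labels)
        assert np.isclose(res.auc, oracle_auc_paircount(scores, labels),
                          atol=1e-12)

    def test_null_auc_within_delong_ci(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = auc(scores, labels)
        assert res.ci[0] <= 0.5 <= res.ci[1]

    def test_delong_se_agrees_with_bootstrap(self):
        rng = np.random.default_rng(8)
        scores = np.concatenate([rng.normal(0.5, 1, 150),
                                 rng.normal(0, 1, 350)])
        labels = np.concatenate([np.ones(150), np.zeros(350)])
        d = auc(scores, labels, ci_method="delong")
        b = auc(scores, labels, ci_method="bootstrap", n_boot=500, seed=1)
        assert abs(d.se - b.se) / d.se < 0.3

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a1 = auc(scores, labels).auc
        a2 = auc(np.exp(3 * scores) + 7, labels).auc
        assert np.isclose(a1, a2, atol=1e-12)


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        t, s = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(s == 1.0)

    def test_hand_product_limit(self):
        t, s = km_curve([1.0, 2.0], [1, 1])
        # S(1) = 1/2, S(2) = 0
        def at(tt):
            return s[np.searchsorted(t, tt, side="right") - 1]
        assert at(1.0) == 0.5
        assert at(2.0) == 0.0

    def test_censoring_mixture(self):
        t, s = km_curve([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        def at(tt):
            return s[np.searchsorted(t, tt, side="right") - 1]
        assert np.isclose(at(1.0), 0.75)
        assert np.isclose(at(3.0), 0.75 * 0.5)

    def test_non_increasing_and_matches_empirical_without_censoring(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(5, 500) + 0.01
        events = np.ones(500, dtype=int)
        t, s = km_curve(times, events)
        assert np.all(np.diff(s) <= 1e-12)
        # no censoring: KM equals the empirical survival function
        for tt in np.percentile(times, [25, 50, 75]):
            emp = (times > tt).mean()
            km_val = s[np.searchsorted(t, tt, side="right") - 1]
            assert np.isclose(km_val, emp, atol=1e-12)


class TestQuantileIncidence:
    def test_two_bins_with_all_events_on_top(self):
        scores = np.arange(1, 11, dtype=float)
        events = (scores > 5).astype(int)
        qi = quantile_incidence(scores, events, q=2)
        assert np.allclose(qi.rates, [0.0, 1.0])
        assert qi.fold_ratio == np.inf

    def test_printed_rates_reproduce_fold(self):
        # top/bottom decile rates 27.3% and 14.3% -> 1.9-fold at 1 d.p.
        n_bin = 1000
        scores = np.repeat(np.arange(10, dtype=float), n_bin)
        events = np.zeros(10 * n_bin, dtype=int)
        events[:143] = 1                       # bottom decile 14.3%
        events[-273:] = 1                      # top decile 27.3%
        qi = quantile_incidence(scores, events, q=10)
        assert np.isclose(qi.rates[0], 0.143)
        assert np.isclose(qi.rates[-1], 0.273)
        assert round(qi.fold_ratio, 1) == 1.9

    def test_null_spread_within_binomial_envelope(self):
        rng = np.random.default_rng(31)
        n, q, p = 5000, 10, 0.2
        scores = rng.uniform(size=n)
        events = (rng.uniform(size=n) < p).astype(int)
        qi = quantile_incidence(scores, events, q=q)
        se = np.sqrt(p * (1 - p) / (n / q))
        assert np.all(np.abs(qi.rates - p) < 4 * se)

    def test_q_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            quantile_incidence([1.0, 2.0], [0, 1], q=1)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError, match="at least q"):
            quantile_incidence([1.0, 2.0], [0, 1], q=3)
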