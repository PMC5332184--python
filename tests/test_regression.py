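"""Weighted regression layer: IPW, IRLS logistic, WLS, FGLS system."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import longmediate as lm
from longmediate.regression import DesignMatrix, _wls


def make_design(X, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    return DesignMatrix(np.asarray(X, dtype=float), names)


class TestComputeIpw:
    def test_standard_weights(self):
        y = np.array([1] * 130 + [0] * 352)
        w = lm.compute_ipw(y, source_noncases=1000)
        assert np.all(w[:130] == 1.0)
        assert w[130] == pytest.approx(1000 / 352, rel=1e-12)

    def test_full_cohort_gives_unit_weights(self):
        y = np.array([1, 0, 0, 0])
        assert np.all(lm.compute_ipw(y, source_noncases=3) == 1.0)

    def test_ten_percent_sampling_fraction(self):
        y = np.array([1, 0])
        assert lm.compute_ipw(y, source_noncases=10)[1] == 10.0

    def test_missing_source_size_instructs_user(self):
        with pytest.raises(ValueError, match="unweighted sensitivity"):
            lm.compute_ipw(np.array([1, 0]), source_noncases=None)

    def test_controls_exceeding_source_rejected(self):
        with pytest.raises(ValueError):
            lm.compute_ipw(np.array([1, 0, 0]), source_noncases=1)


class TestLogisticIrls:
    def _instance(self, n=20, seed=5):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < expit(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])).astype(float)
        return X, y

    def test_matches_statsmodels_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = self._instance()
        fit = lm.fit_logistic_outcome(make_design(X), y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-6)

    def test_matches_generic_optimizer_mle(self):
        X, y = self._instance(seed=7)

        def negll(b):
            eta = X @ b
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

        ref = minimize(negll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        fit = lm.fit_logistic_outcome(make_design(X), y)
        assert np.allclose(fit.params, ref.x, atol=1e-6)

    def test_weighted_fit_matches_statsmodels_freq_weights(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = self._instance(n=60, seed=9)
        w = np.where(y == 1, 1.0, 2.5)
        fit = lm.fit_logistic_outcome(make_design(X), y, weights=w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-6)

    def test_null_data_slopes_near_zero(self):
        rng = np.random.default_rng(11)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = (rng.random(n) < 0.3).astype(float)
        fit = lm.fit_logistic_outcome(make_design(X, ["intercept", "a", "b"]), y)
        for term in ("a", "b"):
            assert abs(fit.coef(term)) < 3 * fit.se(term)

    def test_perfect_separation_raises_with_trace(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        X = np.column_stack([np.ones(20), a])
        y = (a > 0).astype(float)
        with pytest.raises(lm.ConvergenceError) as err:
            lm.fit_logistic_outcome(make_design(X), y)
        assert len(err.value.trace) > 0

    def test_rank_deficiency_names_collinear_term(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        X = np.column_stack([np.ones(30), a, 2 * a])
        y = (rng.random(30) < 0.4).astype(float)
        with pytest.raises(lm.RankDeficiencyError, match="'a'|'dup'") as err:
            lm.fit_logistic_outcome(make_design(X, ["intercept", "a", "dup"]), y)
        assert "intercept" not in str(err.value)

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lm.fit_logistic_outcome(make_design(np.ones((4, 1))), np.array([0, 1, 2, 1.0]))


class TestMediatorAverage:
    def test_unit_weights_reduce_to_ols(self):
        rng = np.random.default_rng(8)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 + 0.25 * X[:, 1] + rng.normal(scale=0.5, size=n)
        fit = lm.fit_mediator_average(make_design(X, ["intercept", "exposure"]), y, np.ones(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.params, beta_ols, atol=1e-10)

    def test_binary_weights_equal_ols_on_subset(self):
        rng = np.random.default_rng(12)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.5 + 0.3 * X[:, 1] + rng.normal(size=n)
        keep = rng.random(n) < 0.6
        w = keep.astype(float) + 1e-12  # strictly positive weights required
        fit = lm.fit_mediator_average(make_design(X), y, w)
        beta_sub, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        assert np.allclose(fit.params, beta_sub, atol=1e-6)

    def test_deterministic_mediator_flags_degenerate_fit(self):
        rng = np.random.default_rng(13)
        abar = rng.normal(size=50)
        X = np.column_stack([np.ones(50), abar])
        fit = lm.fit_mediator_average(make_design(X, ["intercept", "exposure"]), abar, np.ones(50))
        assert fit.coef("exposure") == pytest.approx(1.0, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-16)
        assert any("degenerate" in w for w in fit.warnings)

    def test_wls_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(14)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 - 0.4 * X[:, 1] + rng.normal(size=n)
        w = rng.uniform(0.5, 3.0, size=n)
        fit = lm.fit_mediator_average(make_design(X), y, w)
        ref = sm.WLS(y, X, weights=w).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-10)


def _simulate_system(n, corr, sigma=1.0, seed=21):
    """Three visit-level regressions y_t = 1 + 0.5 x_t + eps, eps ~ MVN."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    L = np.linalg.cholesky(sigma**2 * corr)
    eps = rng.standard_normal((n, 3)) @ L.T
    M = 1.0 + 0.5 * X + eps
    designs = [
        make_design(np.column_stack([np.ones(n), X[:, t]]), ["intercept", "exposure_avg"])
        for t in range(3)
    ]
    return designs, M


class TestMediatorLongitudinal:
    def test_joint_with_identity_corr_reproduces_separate_fits(self):
        corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        designs, M = _simulate_system(500, corr)
        w = np.ones(500)
        sep = lm.fit_mediator_longitudinal(designs, M, w, joint=False)
        fixed = lm.fit_mediator_longitudinal(designs, M, w, joint=True, fixed_corr=np.eye(3))
        assert np.allclose(sep.params, fixed.params, atol=1e-8)

    def test_independent_errors_estimated_near_identity(self):
        designs, M = _simulate_system(5000, np.eye(3))
        fit = lm.fit_mediator_longitudinal(designs, M, np.ones(5000), joint=True)
        off = fit.corr[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3.0 / np.sqrt(5000))

    def test_equicorrelated_variance_of_summed_mediator(self):
        # sigma^2 = 1, off-diagonals 0.5 -> Var(sum M(t)) = 3 + 6 * 0.5 = 6
        corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        designs, M = _simulate_system(20_000, corr)
        fit = lm.fit_mediator_longitudinal(designs, M, np.ones(20_000), joint=True)
        assert fit.var_cum_m == pytest.approx(6.0, abs=0.15)
        assert fit.sigma2 == pytest.approx(1.0, abs=0.05)

    def test_fgls_invariant_to_subject_reordering(self):
        corr = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        designs, M = _simulate_system(400, corr)
        w = np.random.default_rng(5).uniform(1.0, 3.0, size=400)
        fit = lm.fit_mediator_longitudinal(designs, M, w, joint=True)
        perm = np.random.default_rng(6).permutation(400)
        designs_p = [make_design(d.X[perm], d.names) for d in designs]
        fit_p = lm.fit_mediator_longitudinal(designs_p, M[perm], w[perm], joint=True)
        assert np.allclose(fit.params, fit_p.params, atol=1e-10)
        assert np.allclose(fit.corr, fit_p.corr, atol=1e-10)

    def test_missing_mediator_values_rejected(self):
        designs, M = _simulate_system(50, np.eye(3))
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            lm.fit_mediator_longitudinal(designs, M, np.ones(50))

    def test_visit_coef_naming(self):
        designs, M = _simulate_system(200, np.eye(3))
        fit = lm.fit_mediator_longitudinal(designs, M, np.ones(200), joint=False)
        for t in (1, 2, 3):
            assert fit.visit_coef("exposure_avg", t) == pytest.approx(0.5, abs=0.25)


class TestRecoveryOnSyntheticCohort:
    def test_outcome_slopes_recovered_on_full_cohort(self):
        from longmediate.synthetic import OutcomeParams

        cfg = lm.SimConfig(
            n_cohort=50_000,
            sampling=None,
            missingness_rates=(0.0, 0.0, 0.0),
            outcome=OutcomeParams(b_cum_exposure=0.3, b_cum_mediator=0.4, target_prevalence=0.05),
            seed=31,
        )
        cohort, truth = lm.generate_cohort(cfg)
        data = lm.prepare(cohort, lm.AnalysisOptions(standardize=False))
        _, (outcome_fit, mediator_fits) = lm.estimate(
            data,
            method=3,
            options=lm.AnalysisOptions(standardize=False),
            scenario=lm.LongScenario(a_star_history=(2.0, 2.0, 2.0)),
            return_fits=True,
        )
        assert abs(outcome_fit.coef("cum_exposure") - 0.3) < 3 * outcome_fit.se("cum_exposure")
        assert abs(outcome_fit.coef("cum_mediator") - 0.4) < 3 * outcome_fit.se("cum_mediator")
        # per-visit mediator slopes recover the generating 0.26
        for t in (1, 2, 3):
            se = mediator_fits.se(f"exposure_avg@t{t}")
            assert abs(mediator_fits.visit_coef("exposure_avg", t) - 0.26) < 3 * se
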