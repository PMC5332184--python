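"""Closed-form mediation effect expressions and their nesting structure."""

import numpy as np
import pytest

import longmediate as lm
from longmediate.regression import ModelFit


def mk_fit(terms, params, sigma2=None, corr=None, var_cum_m=None, n=100):
    params = np.asarray(params, dtype=float)
    return ModelFit(
        terms=list(terms),
        params=params,
        cov=np.zeros((len(params), len(params))),
        n=n,
        weighted=False,
        sigma2=sigma2,
        corr=corr,
        var_cum_m=var_cum_m,
    )


def avg_outcome(b_ya, b_ym, b_yi=None, b0=0.0):
    terms = ["intercept", "exposure", "mediator"]
    params = [b0, b_ya, b_ym]
    if b_yi is not None:
        terms.append("exposure:mediator")
        params.append(b_yi)
    return mk_fit(terms, params)


def avg_mediator(b_ma, intercept=0.0, sigma2=0.25):
    return mk_fit(["intercept", "exposure"], [intercept, b_ma], sigma2=sigma2)


def long_outcome(b_ya, b_ym, b_yi=None, b0=0.0):
    terms = ["intercept", "cum_exposure", "cum_mediator"]
    params = [b0, b_ya, b_ym]
    if b_yi is not None:
        terms.append("cum_exposure:cum_mediator")
        params.append(b_yi)
    return mk_fit(terms, params)


def long_mediator(slopes, intercepts=(0.0, 0.0, 0.0), sigma2=0.25, corr=None, joint=True):
    terms, params = [], []
    for t, (b0, b) in enumerate(zip(intercepts, slopes), start=1):
        terms += [f"intercept@t{t}", f"exposure_avg@t{t}"]
        params += [b0, b]
    corr = np.eye(3) if corr is None else corr
    var_cum = sigma2 * float(np.ones(3) @ corr @ np.ones(3)) if joint else None
    return mk_fit(terms, params, sigma2=sigma2, corr=corr if joint else None, var_cum_m=var_cum)


class TestMethod1:
    def test_product_of_coefficients_structure(self):
        # components as printed for a typical metabolite row
        eff = lm.effects_method1(avg_outcome(0.264, 0.62), avg_mediator(0.10))
        assert eff.nde == pytest.approx(0.264)
        assert eff.nie == pytest.approx(0.062)
        assert eff.total == pytest.approx(0.326)
        assert eff.percent_rounded == 19

    def test_zero_mediator_outcome_effect_gives_zero_nie(self):
        eff = lm.effects_method1(avg_outcome(0.3, 0.0), avg_mediator(0.5))
        assert eff.nie == 0.0
        assert eff.percent_mediated == pytest.approx(0.0)

    def test_two_unit_contrast(self):
        eff = lm.effects_method1(
            avg_outcome(0.2, 0.5),
            avg_mediator(0.4),
            lm.Scenario(a_star=-1.0, a=1.0),
        )
        assert eff.nde == pytest.approx(0.4)
        assert eff.nie == pytest.approx(0.4)
        assert eff.percent_rounded == 50

    def test_interaction_term_redirects_to_method2(self):
        with pytest.raises(lm.EffectsError, match="method2"):
            lm.effects_method1(avg_outcome(0.2, 0.5, b_yi=0.1), avg_mediator(0.4))

    def test_rare_outcome_guard_warns(self):
        with pytest.warns(UserWarning, match="rare-outcome"):
            lm.effects_method1(avg_outcome(0.2, 0.5), avg_mediator(0.4), prevalence=0.25)


class TestMethod2:
    def test_hand_evaluated_interaction_example(self):
        # b_yi=0.2, b_ym=0, b_ma=0.5, a*=-1, a=0, mu(-1)=0, sigma2=1
        outcome = avg_outcome(0.3, 0.0, b_yi=0.2)
        mediator = mk_fit(["intercept", "exposure"], [0.5, 0.5], sigma2=1.0)  # mu(-1)=0.5-0.5=0
        eff = lm.effects_method2(outcome, mediator, lm.Scenario(a_star=-1.0, a=0.0))
        assert eff.nde == pytest.approx(0.3 - 0.02, abs=1e-12)
        assert eff.nie == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_method1_when_interaction_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b_ya, b_ym, b_ma, b0m = rng.normal(size=4)
            outcome = avg_outcome(b_ya, b_ym)
            mediator = avg_mediator(b_ma, intercept=b0m, sigma2=abs(rng.normal()) + 0.1)
            scen = lm.Scenario(fixed_covariates={})
            e1 = lm.effects_method1(outcome, mediator, scen)
            e2 = lm.effects_method2(outcome, mediator, scen)
            assert e2.nde == pytest.approx(e1.nde, abs=1e-12)
            assert e2.nie == pytest.approx(e1.nie, abs=1e-12)

    def test_total_is_sum_of_components(self):
        eff = lm.effects_method2(avg_outcome(0.1, 0.2, b_yi=0.15), avg_mediator(0.3))
        assert eff.total == pytest.approx(eff.nde + eff.nie, abs=0)

    def test_covariate_fixing_enters_reference_mediator_mean(self):
        outcome = avg_outcome(0.1, 0.2, b_yi=0.5)
        mediator = mk_fit(["intercept", "exposure", "age"], [0.0, 0.3, 0.02], sigma2=0.2)
        e_ref = lm.effects_method2(outcome, mediator, lm.Scenario())
        e_age = lm.effects_method2(
            outcome, mediator, lm.Scenario(fixed_covariates={"age": 30.0})
        )
        # mu(a*) differs by 0.02 * 30, scaled through b_yi * contrast
        assert e_age.nde - e_ref.nde == pytest.approx(0.5 * 0.6, abs=1e-12)

    def test_missing_sigma2_rejected(self):
        with pytest.raises(lm.EffectsError, match="sigma2"):
            lm.effects_method2(avg_outcome(0.1, 0.2, b_yi=0.1), mk_fit(["intercept", "exposure"], [0, 0.3]))

    def test_contrast_linearity_without_interaction(self):
        outcome = avg_outcome(0.2, 0.4)
        mediator = avg_mediator(0.3)
        e1 = lm.effects_method1(outcome, mediator, lm.Scenario(a_star=0.0, a=1.0))
        e2 = lm.effects_method1(outcome, mediator, lm.Scenario(a_star=0.0, a=2.0))
        assert e2.nde == pytest.approx(2 * e1.nde)
        assert e2.nie == pytest.approx(2 * e1.nie)


class TestMethod3:
    def test_cumulative_contrast_arithmetic(self):
        eff = lm.effects_method3(long_outcome(0.088, 0.1), long_mediator((0.0, 0.0, 0.0), joint=False))
        assert eff.nde == pytest.approx(3 * 0.088, abs=1e-12)

    def test_zero_mediator_slopes_give_zero_nie(self):
        eff = lm.effects_method3(long_outcome(0.1, 0.4), long_mediator((0.0, 0.0, 0.0), joint=False))
        assert eff.nie == 0.0

    def test_first_visit_only_shift_propagates_through_running_average(self):
        # delta=(1,0,0): avg shifts are (1, 1/2, 1/3)
        b, b_ym = 0.3, 0.4
        eff = lm.effects_method3(
            long_outcome(0.1, b_ym),
            long_mediator((b, b, b), joint=False),
            lm.LongScenario(delta=(1.0, 0.0, 0.0)),
        )
        assert eff.nie == pytest.approx(b_ym * b * (1 + 0.5 + 1 / 3), abs=1e-12)

    def test_interaction_term_redirects_to_method4(self):
        with pytest.raises(lm.EffectsError, match="method4"):
            lm.effects_method3(long_outcome(0.1, 0.2, b_yi=0.05), long_mediator((0.1,) * 3))

    def test_incomplete_mediator_system_rejected(self):
        partial = mk_fit(["intercept@t1", "exposure_avg@t1"], [0.0, 0.2], sigma2=0.2)
        with pytest.raises(lm.EffectsError, match="visit"):
            lm.effects_method3(long_outcome(0.1, 0.2), partial)


class TestMethod4:
    def test_reduces_to_method3_with_zero_interaction(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b_ya, b_ym = rng.normal(size=2)
            slopes = rng.normal(size=3)
            outcome = long_outcome(b_ya, b_ym)
            system = long_mediator(slopes, sigma2=abs(rng.normal()) + 0.1)
            scen = lm.LongScenario()
            e3 = lm.effects_method3(outcome, system, scen)
            e4 = lm.effects_method4(outcome, system, scen)
            assert e4.nde == pytest.approx(e3.nde, abs=1e-10)
            assert e4.nie == pytest.approx(e3.nie, abs=1e-10)

    def test_equicorrelated_variance_enters_quadratic_term(self):
        # sigma2=1, off-diagonals 0.5 -> V = 6 in the NDE quadratic term
        corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        system = long_mediator((0.0, 0.0, 0.0), sigma2=1.0, corr=corr)
        assert system.var_cum_m == pytest.approx(6.0)
        b_yi = 0.1
        scen = lm.LongScenario(delta=(1.0, 1.0, 1.0), a_star_history=(0.0, 0.0, 0.0))
        eff = lm.effects_method4(long_outcome(0.0, 0.0, b_yi=b_yi), system, scen)
        # nde = b_yi * (mu_cum + 0) * 3 + 0.5 * b_yi^2 * V * (9 - 0); mu_cum = 0
        assert eff.nde == pytest.approx(0.5 * b_yi**2 * 6.0 * 9.0, abs=1e-12)

    def test_null_outcome_model_gives_zero_effects(self):
        eff = lm.effects_method4(long_outcome(0.0, 0.0, b_yi=0.0), long_mediator((0.3,) * 3))
        assert eff.nde == 0.0 and eff.nie == 0.0

    def test_separate_fits_without_joint_variance_rejected(self):
        with pytest.raises(lm.EffectsError, match="joint"):
            lm.effects_method4(
                long_outcome(0.1, 0.2, b_yi=0.05), long_mediator((0.2,) * 3, joint=False)
            )

    def test_closed_form_agrees_with_monte_carlo_gformula(self):
        # dual route: rare-outcome closed form vs exact-logit simulation
        corr = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        outcome = long_outcome(0.08, 0.12, b_yi=0.01, b0=-7.0)
        system = long_mediator(
            (0.25, 0.25, 0.25), intercepts=(2.8, 2.8, 2.8), sigma2=0.36, corr=corr
        )
        scen = lm.LongScenario(delta=(1.0, 1.0, 1.0), a_star_history=(2.0, 2.0, 2.0))
        closed = lm.effects_method4(outcome, system, scen)
        mc, ses = lm.effects_gformula_mc(
            outcome, system, scen, n_draws=400_000, rng=np.random.default_rng(17)
        )
        # small residual gap is the rare-outcome approximation itself
        assert mc.nde == pytest.approx(closed.nde, abs=0.01 + 3 * ses["nde_mc_se"])
        assert mc.nie == pytest.approx(closed.nie, abs=0.01 + 3 * ses["nie_mc_se"])


class TestProportionMediated:
    def test_opposite_signs_not_interpretable(self):
        eff = lm.MediationEffects(nde=0.3, nie=-0.1, method=1)
        assert eff.percent_mediated is None
        assert not eff.percent_interpretable
        assert eff.percent_rounded is None

    def test_shared_sign_reported(self):
        pm, ok = lm.proportion_mediated(0.062, 0.326)
        assert ok and pm == pytest.approx(100 * 0.062 / 0.326)

    def test_degenerate_scenario_rejected(self):
        with pytest.raises(lm.EffectsError):
            lm.Scenario(a_star=0.5, a=0.5)

    def test_long_scenario_needs_a_shift(self):
        with pytest.raises(lm.EffectsError):
            lm.LongScenario(delta=(0.0, 0.0, 0.0))
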