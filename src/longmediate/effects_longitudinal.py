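"""Randomized-interventional-analogue effects from the longitudinal fits.

With exposure and mediator measured at three visits and a non-time-varying
binary outcome, natural direct/indirect effects are replaced by their
randomized interventional analogues: the mediator is drawn from its
counterfactual distribution under a reference exposure history rather than
fixed at an individual counterfactual value.  Without time-varying
confounders the g-formula for these analogues reduces to the longitudinal
mediation formula, and with marginal structural models that are linear
(mediator) and logistic (rare outcome) the integrals are available in
closed form.

``effects_method3`` uses the no-interaction marginal structural models
(cumulative exposure and mediator in the outcome model; running exposure
average in the per-visit mediator models).  ``effects_method4`` adds a
cum(a) x cum(m) interaction, which brings the variance of the summed
mediator, Var(M(1)+M(2)+M(3)) = sigma2 * 1' Sigma 1, into the direct
effect -- the reason the mediator system must be estimated jointly.

``effects_gformula_mc`` evaluates the same interventional contrasts by
brute-force Monte Carlo (drawing mediator vectors from the fitted
multivariate normal and averaging exact logistic probabilities).  It does
not use the rare-outcome approximation, so it serves as the independent
arbiter for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .effects_average import EffectsError, MediationEffects, _check_rare
from .regression import ModelFit

N_VISITS = 3
CUM_INTERACTION = "cum_exposure:cum_mediator"


@dataclass
class LongScenario:
    """Exposure-history contrast for the longitudinal methods.

    ``delta`` is the per-visit exposure increment (default one standardized
    ln-unit at every visit, i.e. "an ln-unit increase in exposure across
    all three time points"); ``a_star_history`` the reference history it is
    added to.  ``fixed_covariates`` maps subject-level mediator-model term
    names to fixed values; ``fixed_specific_gravity`` gives the per-visit
    specific-gravity values used when evaluating the reference mediator
    mean (scalar broadcasts).
    """

    delta: tuple[float, ...] = (1.0, 1.0, 1.0)
    a_star_history: tuple[float, ...] = (-1.0, -1.0, -1.0)
    fixed_covariates: dict[str, float] = field(default_factory=dict)
    fixed_specific_gravity: tuple[float, ...] | float = 0.0

    def __post_init__(self) -> None:
        if len(self.delta) != N_VISITS or len(self.a_star_history) != N_VISITS:
            raise EffectsError("delta and a_star_history must have one entry per visit")
        if not any(d != 0.0 for d in self.delta):
            raise EffectsError("at least one per-visit increment must be nonzero")

    @property
    def a_history(self) -> tuple[float, ...]:
        return tuple(a + d for a, d in zip(self.a_star_history, self.delta))

    def sg_at(self, t: int) -> float:
        sg = self.fixed_specific_gravity
        return float(sg) if np.isscalar(sg) else float(sg[t - 1])


def _running_avg(history: tuple[float, ...]) -> list[float]:
    return [float(np.mean(history[:t])) for t in range(1, N_VISITS + 1)]


def _visit_terms(fit: ModelFit, t: int) -> list[str]:
    suffix = f"@t{t}"
    return [term[: -len(suffix)] for term in fit.terms if term.endswith(suffix)]


def _check_mediator_fit(fit: ModelFit) -> None:
    for t in range(1, N_VISITS + 1):
        if not fit.has_term(f"exposure_avg@t{t}"):
            raise EffectsError(
                f"mediator system lacks an exposure_avg coefficient for visit {t}; "
                "fit all three visit regressions"
            )


def _mediator_shift(mediator_fits: ModelFit, scenario: LongScenario) -> list[float]:
    """Per-visit induced mediator shift: beta_ma(t) * mean(delta(1..t))."""
    davg = _running_avg(scenario.delta)
    return [
        mediator_fits.visit_coef("exposure_avg", t) * davg[t - 1] for t in range(1, N_VISITS + 1)
    ]


def _mediator_mean(mediator_fits: ModelFit, history: tuple[float, ...], scenario: LongScenario, t: int) -> float:
    """E[M(t) | exposure history, fixed covariates]."""
    avg_a = _running_avg(history)[t - 1]
    mu = mediator_fits.visit_coef("intercept", t) + mediator_fits.visit_coef("exposure_avg", t) * avg_a
    for term in _visit_terms(mediator_fits, t):
        if term in ("intercept", "exposure_avg"):
            continue
        if term == "specific_gravity":
            value = scenario.sg_at(t)
        else:
            value = scenario.fixed_covariates.get(term, 0.0)
        mu += mediator_fits.visit_coef(term, t) * value
    return mu


def effects_method3(
    outcome_fit: ModelFit,
    mediator_fits: ModelFit,
    scenario: LongScenario | None = None,
    prevalence: float | None = None,
    rare_ceiling: float = 0.10,
) -> MediationEffects:
    """Longitudinal decomposition without exposure-mediator interaction.

    nde = b_ya * sum_t delta(t); nie = b_ym * sum_t beta_ma(t) *
    mean(delta(1..t)) -- the induced mediator shift propagated through the
    cumulative-mediator outcome coefficient.
    """
    scenario = scenario or LongScenario()
    if outcome_fit.has_term(CUM_INTERACTION):
        raise EffectsError(
            "outcome model contains a cum(a):cum(m) interaction; use effects_method4"
        )
    _check_mediator_fit(mediator_fits)
    _check_rare(prevalence, rare_ceiling)
    nde = outcome_fit.coef("cum_exposure") * float(np.sum(scenario.delta))
    nie = outcome_fit.coef("cum_mediator") * float(np.sum(_mediator_shift(mediator_fits, scenario)))
    return MediationEffects(nde=nde, nie=nie, method=3)


def effects_method4(
    outcome_fit: ModelFit,
    mediator_fits: ModelFit,
    scenario: LongScenario | None = None,
    prevalence: float | None = None,
    rare_ceiling: float = 0.10,
) -> MediationEffects:
    """Longitudinal decomposition with a cum(a) x cum(m) interaction.

    Mirrors the average-based interaction expressions with cumulative sums
    as the working variables: with mu_cum(a*) = sum_t E[M(t) | reference
    history, fixed covariates] and V = Var(sum_t M(t)) = sigma2 * 1'Sigma 1
    from the jointly estimated mediator system,

        nde = [b_ya + b_yi (mu_cum(a*) + b_ym V)] (cum_a - cum_a*)
              + 1/2 b_yi^2 V (cum_a^2 - cum_a*^2)
        nie = (b_ym + b_yi cum_a) * sum_t beta_ma(t) mean(delta(1..t))

    With b_yi = 0 this reduces to :func:`effects_method3`.
    """
    scenario = scenario or LongScenario()
    _check_mediator_fit(mediator_fits)
    if mediator_fits.var_cum_m is None:
        raise EffectsError(
            "mediator system provides no Var(sum M(t)); fit with joint=True "
            "(generalized least squares across visits)"
        )
    _check_rare(prevalence, rare_ceiling)
    cum_star = float(np.sum(scenario.a_star_history))
    cum_a = float(np.sum(scenario.a_history))
    b_ya = outcome_fit.coef("cum_exposure")
    b_ym = outcome_fit.coef("cum_mediator")
    b_yi = outcome_fit.coef(CUM_INTERACTION, default=0.0)
    V = mediator_fits.var_cum_m
    mu_cum_star = sum(
        _mediator_mean(mediator_fits, scenario.a_star_history, scenario, t)
        for t in range(1, N_VISITS + 1)
    )
    nde = (b_ya + b_yi * (mu_cum_star + b_ym * V)) * (cum_a - cum_star) + 0.5 * b_yi**2 * V * (
        cum_a**2 - cum_star**2
    )
    nie = (b_ym + b_yi * cum_a) * float(np.sum(_mediator_shift(mediator_fits, scenario)))
    return MediationEffects(nde=nde, nie=nie, method=4)


# ---------------------------------------------------------------------------
# Monte-Carlo g-formula arbiter
# ---------------------------------------------------------------------------


def gformula_mc_core(
    outcome_intercept: float,
    b_ya: float,
    b_ym: float,
    b_yi: float,
    outcome_offset: float,
    mediator_means_star: np.ndarray,
    mediator_means_a: np.ndarray,
    sigma2: float,
    corr: np.ndarray,
    cum_a_star: float,
    cum_a: float,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
    n_batches: int = 20,
) -> tuple[float, float, float, float]:
    """Interventional NDE/NIE by simulation from explicit coefficients.

    Draws mediator vectors M ~ MVN(mu(history), sigma2 * corr) under the
    reference and shifted exposure histories (common random numbers),
    averages exact logistic outcome probabilities, and contrasts marginal
    log-odds.  Returns (nde, nie, nde_mc_se, nie_mc_se) with Monte-Carlo
    standard errors from batch means.
    """
    rng = rng or np.random.default_rng()
    L = np.linalg.cholesky(sigma2 * corr)
    eps = rng.standard_normal((n_draws, N_VISITS)) @ L.T

    def prob(cum_exposure: float, means: np.ndarray) -> np.ndarray:
        cum_m = (means + eps).sum(axis=1)
        eta = (
            outcome_intercept
            + b_ya * cum_exposure
            + b_ym * cum_m
            + b_yi * cum_exposure * cum_m
            + outcome_offset
        )
        return expit(eta)

    p00 = prob(cum_a_star, mediator_means_star)
    p10 = prob(cum_a, mediator_means_star)
    p11 = prob(cum_a, mediator_means_a)

    def contrast(px: np.ndarray, py: np.ndarray) -> tuple[float, float]:
        est = float(logit(px.mean()) - logit(py.mean()))
        splits = [
            float(logit(bx.mean()) - logit(by.mean()))
            for bx, by in zip(np.array_split(px, n_batches), np.array_split(py, n_batches))
        ]
        se = float(np.std(splits, ddof=1) / np.sqrt(n_batches))
        return est, se

    nde, nde_se = contrast(p10, p00)
    nie, nie_se = contrast(p11, p10)
    return nde, nie, nde_se, nie_se


def effects_gformula_mc(
    outcome_fit: ModelFit,
    mediator_fits: ModelFit,
    scenario: LongScenario | None = None,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[MediationEffects, dict[str, float]]:
    """Monte-Carlo evaluation of the Method 3/4 contrasts from fitted models.

    Uses the fitted mediator system's error law (sigma2, Sigma) and the
    fitted outcome model with exact logistic probabilities; covariates are
    fixed as in ``scenario``.  Returns the effects plus the Monte-Carlo
    standard errors.  Intended as a cross-check on the closed forms, which
    additionally invoke the rare-outcome approximation.
    """
    scenario = scenario or LongScenario()
    _check_mediator_fit(mediator_fits)
    if mediator_fits.sigma2 is None:
        raise EffectsError("mediator system lacks sigma2")
    corr = mediator_fits.corr if mediator_fits.corr is not None else np.eye(N_VISITS)
    means_star = np.array(
        [
            _mediator_mean(mediator_fits, scenario.a_star_history, scenario, t)
            for t in range(1, N_VISITS + 1)
        ]
    )
    means_a = np.array(
        [
            _mediator_mean(mediator_fits, scenario.a_history, scenario, t)
            for t in range(1, N_VISITS + 1)
        ]
    )
    offset = 0.0
    for term, beta in zip(outcome_fit.terms, outcome_fit.params):
        if term in ("intercept", "cum_exposure", "cum_mediator", CUM_INTERACTION):
            continue
        if term == "specific_gravity":
            value = float(np.mean(np.atleast_1d(scenario.fixed_specific_gravity)))
        else:
            value = scenario.fixed_covariates.get(term, 0.0)
        offset += float(beta) * value
    nde, nie, nde_se, nie_se = gformula_mc_core(
        outcome_intercept=outcome_fit.coef("intercept"),
        b_ya=outcome_fit.coef("cum_exposure"),
        b_ym=outcome_fit.coef("cum_mediator"),
        b_yi=outcome_fit.coef(CUM_INTERACTION, default=0.0),
        outcome_offset=offset,
        mediator_means_star=means_star,
        mediator_means_a=means_a,
        sigma2=mediator_fits.sigma2,
        corr=corr,
        cum_a_star=float(np.sum(scenario.a_star_history)),
        cum_a=float(np.sum(scenario.a_history)),
        n_draws=n_draws,
        rng=rng,
    )
    eff = MediationEffects(nde=nde, nie=nie, method=4)
    return eff, {"nde_mc_se": nde_se, "nie_mc_se": nie_se}
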