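"""Natural direct and indirect effects from the average-based fits.

Both estimators work on the log-odds-ratio scale under the rare-outcome
approximation: with an uncommon outcome the odds ratio approximates the
risk ratio, which licenses the closed-form expressions for the natural
direct effect (NDE) and natural indirect effect (NIE) from a logistic
outcome model combined with a linear mediator model.  ``effects_method1``
handles the no-interaction decomposition (NIE is the familiar product of
coefficients); ``effects_method2`` allows an exposure-mediator interaction,
in which case the NDE depends on the covariate levels at which it is
evaluated and on the mediator residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .regression import ModelFit

INTERACTION_TERM = "exposure:mediator"


class EffectsError(ValueError):
    pass


@dataclass
class Scenario:
    """Exposure contrast and covariate-fixing rule for the average methods.

    The default contrast is a 1-SD increase on the standardized scale, from
    the mean minus one SD (``a_star = -1``) to the mean (``a = 0``).
    ``fixed_covariates`` maps mediator-model term names to the values at
    which covariates are fixed (continuous terms at their arithmetic means;
    indicator terms at 0, i.e. the reference level); terms not listed are
    fixed at 0.
    """

    a_star: float = -1.0
    a: float = 0.0
    fixed_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a == self.a_star:
            raise EffectsError("scenario requires a != a_star")


@dataclass
class MediationEffects:
    """NDE, NIE and total effect on the log-odds-ratio scale.

    ``total = nde + nie`` by construction.  ``percent_mediated`` is
    100 * nie / total, reported unrounded and only when NIE and the total
    effect share sign; otherwise it is None and
    ``percent_interpretable`` is False (a proportion mediated outside
    [0, 100] has no mediation interpretation).  ``ci`` holds percentile
    bootstrap intervals keyed by component once inference has run; the
    percent-mediated interval is descriptive only (a ratio of bootstrap
    replicates).
    """

    nde: float
    nie: float
    method: int
    total: float = None  # type: ignore[assignment]
    percent_mediated: float | None = None
    percent_interpretable: bool = True
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int | None = None

    def __post_init__(self) -> None:
        if self.total is None:
            self.total = self.nde + self.nie
        if self.percent_mediated is None:
            self.percent_mediated, self.percent_interpretable = proportion_mediated(
                self.nie, self.total
            )

    @property
    def percent_rounded(self) -> int | None:
        if self.percent_mediated is None:
            return None
        return int(round(self.percent_mediated))

    def with_ci(self, ci: dict[str, tuple[float, float]], n_boot: int) -> "MediationEffects":
        return replace(self, ci=ci, n_boot=n_boot)


def proportion_mediated(nie: float, total: float) -> tuple[float | None, bool]:
    """Percent mediated, or (None, False) when it is not interpretable."""
    if total == 0.0:
        return (0.0, True) if nie == 0.0 else (None, False)
    pm = 100.0 * nie / total
    if nie * total < 0:
        return None, False
    return pm, True


def _check_rare(prevalence: float | None, ceiling: float) -> None:
    if prevalence is not None and prevalence > ceiling:
        warnings.warn(
            f"outcome prevalence {prevalence:.3f} exceeds the rare-outcome ceiling "
            f"{ceiling:.2f}; the odds-ratio mediation expressions may be biased",
            stacklevel=3,
        )


def _fixed_sum(fit: ModelFit, fixed: dict[str, float], skip: tuple[str, ...]) -> float:
    """Sum of covariate coefficients times their fixed values."""
    total = 0.0
    for term, beta in zip(fit.terms, fit.params):
        if term in skip:
            continue
        total += float(beta) * fixed.get(term, 0.0)
    return total


def effects_method1(
    outcome_fit: ModelFit,
    mediator_fit: ModelFit,
    scenario: Scenario | None = None,
    prevalence: float | None = None,
    rare_ceiling: float = 0.10,
) -> MediationEffects:
    """Average-based decomposition without exposure-mediator interaction.

    nde = beta_ya * (a - a*), nie = beta_ym * beta_ma * (a - a*): the
    product-of-coefficients form, valid for a rare outcome.
    """
    scenario = scenario or Scenario()
    if outcome_fit.has_term(INTERACTION_TERM):
        raise EffectsError(
            "outcome model contains an exposure:mediator interaction; use effects_method2"
        )
    _check_rare(prevalence, rare_ceiling)
    contrast = scenario.a - scenario.a_star
    nde = outcome_fit.coef("exposure") * contrast
    nie = outcome_fit.coef("mediator") * mediator_fit.coef("exposure") * contrast
    return MediationEffects(nde=nde, nie=nie, method=1)


def effects_method2(
    outcome_fit: ModelFit,
    mediator_fit: ModelFit,
    scenario: Scenario | None = None,
    prevalence: float | None = None,
    rare_ceiling: float = 0.10,
) -> MediationEffects:
    """Average-based decomposition allowing exposure-mediator interaction.

    With mu(a*) the expected mediator at the reference exposure and fixed
    covariates, and sigma2 the mediator residual variance,

        nde = [b_ya + b_yi (mu(a*) + b_ym sigma2)] (a - a*)
              + 1/2 b_yi^2 sigma2 (a^2 - a*^2)
        nie = (b_ym b_ma + b_yi b_ma a) (a - a*)

    With b_yi = 0 this reduces exactly to :func:`effects_method1`.
    """
    scenario = scenario or Scenario()
    if mediator_fit.sigma2 is None:
        raise EffectsError("mediator fit lacks a residual variance (sigma2)")
    _check_rare(prevalence, rare_ceiling)
    a, a_star = scenario.a, scenario.a_star
    b_ya = outcome_fit.coef("exposure")
    b_ym = outcome_fit.coef("mediator")
    b_yi = outcome_fit.coef(INTERACTION_TERM, default=0.0)
    b_ma = mediator_fit.coef("exposure")
    sigma2 = mediator_fit.sigma2
    mu_star = (
        mediator_fit.coef("intercept")
        + b_ma * a_star
        + _fixed_sum(mediator_fit, scenario.fixed_covariates, skip=("intercept", "exposure"))
    )
    nde = (b_ya + b_yi * (mu_star + b_ym * sigma2)) * (a - a_star) + 0.5 * b_yi**2 * sigma2 * (
        a**2 - a_star**2
    )
    nie = (b_ym * b_ma + b_yi * b_ma * a) * (a - a_star)
    return MediationEffects(nde=nde, nie=nie, method=2)
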