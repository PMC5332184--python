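"""Synthetic cohorts with known ground-truth mediation effects.

The generator emulates the statistical structure the analysis assumes: a
source pregnancy cohort in which each subject has three visits with a
log-normal urinary exposure biomarker (exchangeable within-subject
correlation), a urine-dilution proxy (specific gravity) correlated with the
biomarkers, a log mediator biomarker that depends linearly on the running
average of log exposure with multivariate-normal errors (common variance,
unit-diagonal correlation), and a rare binary outcome that is logistic in
cumulative log exposure and cumulative log mediator, optionally with their
interaction.  A nested case-control subsample is drawn (all or a requested
number of cases, controls at random), visit-level records are deleted
completely at random, and the generating coefficients are returned so that
parameter-recovery tests have a closed-form truth.

Default parameter values describe the emulated study conditions: a source
cohort of 2,000 pregnancies with 8% outcome prevalence from which 130 cases
and 352 controls are sampled; log-exposure SD 1 with within-subject
correlation 0.5; mediator slope 0.26 per ln-unit of running-average
exposure with residual SD 0.6 and error correlation 0.4; outcome slopes
0.088 and 0.14 per cumulative ln-unit of exposure and mediator; and
visit-level missingness rates (0.015, 0.125, 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .effects_longitudinal import LongScenario, gformula_mc_core
from .preprocess import CohortTable, N_VISITS, VISITS


class SimulationError(ValueError):
    pass


class InfeasibleSamplingError(SimulationError):
    """Fewer cases realized in the source cohort than requested."""


# -- categorical covariate distributions (majority reference level) ---------

CATEGORICAL_LEVELS: dict[str, tuple[tuple[str, float], ...]] = {
    "race": (("white", 0.58), ("african_american", 0.16), ("other", 0.26)),
    "education": (
        ("high_school", 0.12),
        ("technical_school", 0.13),
        ("some_college", 0.25),
        ("college_graduate", 0.50),
    ),
    "insurance": (("private", 0.85), ("public", 0.15)),
    "bmi_category": (("lt25", 0.55), ("b25_30", 0.25), ("b30plus", 0.20)),
}

AGE_MEAN, AGE_SD = 32.0, 4.5


def _exchangeable(rho: float, k: int = N_VISITS) -> np.ndarray:
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


@dataclass
class ExposureParams:
    """Per-visit mean/SD of log exposure and within-subject correlation."""

    mean: tuple[float, ...] = (2.0, 2.0, 2.0)
    sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    corr: float = 0.5


@dataclass
class MediatorParams:
    """Per-visit linear model for the log mediator.

    log M(t) = intercept(t) + slope_exposure(t) * avg[log A(1..t)]
               + slope_sg * (L(t) - sg_mean) + covariate effects + eps(t),
    eps ~ MVN(0, sigma^2 * error_corr), unit-diagonal error_corr.
    Covariate effects are keyed by design-term name (``age_c`` is age
    centered at its generating mean; indicator terms like
    ``race_african_american``).
    """

    intercept: tuple[float, ...] = (2.8, 2.8, 2.8)
    slope_exposure: tuple[float, ...] = (0.26, 0.26, 0.26)
    slope_sg: float = 10.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age_c": -0.002,
            "race_african_american": 0.08,
            "bmi_category_b30plus": 0.10,
        }
    )
    sigma: float = 0.6
    error_corr: float | np.ndarray = 0.4

    def corr_matrix(self) -> np.ndarray:
        if np.isscalar(self.error_corr):
            mat = _exchangeable(float(self.error_corr))
        else:
            mat = np.asarray(self.error_corr, dtype=float)
        if mat.shape != (N_VISITS, N_VISITS) or not np.allclose(mat, mat.T):
            raise SimulationError("error correlation must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(mat), 1.0):
            raise SimulationError("error correlation must have unit diagonal")
        if np.min(np.linalg.eigvalsh(mat)) <= 0:
            raise SimulationError("error correlation must be positive definite")
        return mat


@dataclass
class OutcomeParams:
    """Logistic outcome model on cumulative log biomarkers.

    logit P(Y=1) = intercept + b_cum_exposure * cum(log A)
                   + b_cum_mediator * cum(log M)
                   + b_interaction * cum(log A) * cum(log M)
                   + b_sg * (Lbar - sg_mean) + covariate effects.

    When ``intercept`` is None it is solved numerically so that the
    expected full-cohort prevalence equals ``target_prevalence``.
    """

    b_cum_exposure: float = 0.088
    b_cum_mediator: float = 0.14
    b_interaction: float = 0.0
    b_sg: float = 2.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age_c": 0.01, "race_african_american": 0.25, "insurance_public": 0.2}
    )
    intercept: float | None = None
    target_prevalence: float = 0.08


@dataclass
class SamplingPlan:
    """Nested case-control subsample sizes (None keeps the full cohort)."""

    n_cases: int = 130
    n_controls: int = 352


@dataclass
class SimConfig:
    n_cohort: int = 2000
    n_visits: int = N_VISITS
    exposure: ExposureParams = field(default_factory=ExposureParams)
    mediator: MediatorParams = field(default_factory=MediatorParams)
    outcome: OutcomeParams = field(default_factory=OutcomeParams)
    sampling: SamplingPlan | None = field(default_factory=SamplingPlan)
    missingness_rates: tuple[float, ...] = (0.015, 0.125, 0.15)
    sg_mean: float = 1.015
    sg_sd: float = 0.0075
    sg_corr: float = 0.3
    rarity_ceiling: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohort <= 0:
            raise SimulationError("n_cohort must be positive")
        if self.n_visits != N_VISITS:
            raise SimulationError("only three-visit cohorts are supported")
        if not (0.0 <= self.exposure.corr < 1.0):
            raise SimulationError("exposure correlation must be in [0, 1)")
        if any(not (0.0 <= r < 1.0) for r in self.missingness_rates):
            raise SimulationError("missingness rates must be in [0, 1)")
        if len(self.missingness_rates) != N_VISITS:
            raise SimulationError("one missingness rate per visit is required")
        self.mediator.corr_matrix()
        if self.outcome.intercept is None and not (0.0 < self.outcome.target_prevalence <= self.rarity_ceiling):
            raise SimulationError(
                f"target prevalence {self.outcome.target_prevalence} must lie in "
                f"(0, rarity ceiling {self.rarity_ceiling}]"
            )


@dataclass
class SimTruth:
    """Generating truths for the default unit-shift scenario.

    ``true_nde`` and ``true_nie`` are on the log-odds scale for a 1 ln-unit
    exposure increase at every visit, in closed form under the rare-outcome
    approximation when the generating interaction is zero (None otherwise;
    use :func:`true_effects_mc`).
    """

    true_nde: float | None
    true_nie: float | None
    intercept: float
    expected_prevalence: float
    realized_prevalence: float
    source_cases: int
    source_noncases: int
    config: SimConfig

    def as_dict(self) -> dict:
        d = {
            "true_nde": self.true_nde,
            "true_nie": self.true_nie,
            "intercept": self.intercept,
            "expected_prevalence": self.expected_prevalence,
            "realized_prevalence": self.realized_prevalence,
            "source_cases": self.source_cases,
            "source_noncases": self.source_noncases,
        }
        d["config"] = asdict(self.config)
        return d


def closed_form_truth(config: SimConfig, delta: tuple[float, ...] = (1.0, 1.0, 1.0)) -> tuple[float, float]:
    """Rare-outcome closed-form NDE/NIE for a per-visit exposure shift.

    Valid only when the generating interaction coefficient is zero:
    nde = b_ya * sum(delta); nie = b_ym * sum_t slope(t) * mean(delta(1..t)).
    """
    if config.outcome.b_interaction != 0.0:
        raise SimulationError("closed-form truth requires a zero interaction coefficient")
    nde = config.outcome.b_cum_exposure * float(np.sum(delta))
    shifts = [
        config.mediator.slope_exposure[t - 1] * float(np.mean(delta[:t]))
        for t in range(1, N_VISITS + 1)
    ]
    nie = config.outcome.b_cum_mediator * float(np.sum(shifts))
    return nde, nie


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {
        "age": np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n).round(1), 18.0, 45.0)
    }
    for name, levels in CATEGORICAL_LEVELS.items():
        labels = [lv for lv, _ in levels]
        probs = [p for _, p in levels]
        cols[name] = rng.choice(labels, size=n, p=probs)
    return pd.DataFrame(cols)


def _covariate_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Generating-model design: centered age plus indicator terms."""
    columns = [("age_c", (cov["age"] - AGE_MEAN).to_numpy(dtype=float))]
    for name, levels in CATEGORICAL_LEVELS.items():
        for level, _ in levels[1:]:
            columns.append((f"{name}_{level}", (cov[name] == level).to_numpy(dtype=float)))
    names = [c for c, _ in columns]
    X = np.column_stack([v for _, v in columns])
    return X, names


def _effects_vector(effects: Mapping[str, float], names: list[str]) -> np.ndarray:
    unknown = set(effects) - set(names)
    if unknown:
        raise SimulationError(f"unknown covariate effect term(s): {sorted(unknown)}")
    return np.array([effects.get(n, 0.0) for n in names])


def generate_cohort(config: SimConfig) -> tuple[CohortTable, SimTruth]:
    """Simulate a source cohort and return its case-control subsample.

    The returned :class:`~longmediate.preprocess.CohortTable` has missing
    visits encoded as absent rows, subject weights reflecting the sampling
    fractions (cases weight 1 when all cases are taken; controls weight
    source-noncases / controls-sampled), and the accompanying
    :class:`SimTruth` records generating coefficients, the solved outcome
    intercept and the sampling denominators for IPW.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cohort
    exp_p, med_p, out_p = config.exposure, config.mediator, config.outcome

    cov = _draw_covariates(n, rng)
    Xv, names = _covariate_design(cov)
    med_cov = Xv @ _effects_vector(med_p.covariate_effects, names)
    out_cov = Xv @ _effects_vector(out_p.covariate_effects, names)

    # log exposure: multivariate normal, exchangeable correlation
    sd = np.asarray(exp_p.sd, dtype=float)
    cov_a = np.outer(sd, sd) * _exchangeable(exp_p.corr)
    a = rng.multivariate_normal(np.asarray(exp_p.mean, dtype=float), cov_a, size=n, method="cholesky")

    # specific gravity: dilution proxy correlated with the exposure z-score
    z_a = (a - np.asarray(exp_p.mean)) / sd
    sg_noise = rng.standard_normal((n, N_VISITS))
    sg = config.sg_mean + config.sg_sd * (
        config.sg_corr * z_a + np.sqrt(1.0 - config.sg_corr**2) * sg_noise
    )

    # log mediator: running-average exposure effect + MVN errors
    avg_a = np.cumsum(a, axis=1) / np.arange(1, N_VISITS + 1)
    L = np.linalg.cholesky(med_p.sigma**2 * med_p.corr_matrix())
    eps = rng.standard_normal((n, N_VISITS)) @ L.T
    m = (
        np.asarray(med_p.intercept)
        + np.asarray(med_p.slope_exposure) * avg_a
        + med_p.slope_sg * (sg - config.sg_mean)
        + med_cov[:, None]
        + eps
    )

    # outcome: logistic in cumulative log biomarkers
    cum_a, cum_m = a.sum(axis=1), m.sum(axis=1)
    eta = (
        out_p.b_cum_exposure * cum_a
        + out_p.b_cum_mediator * cum_m
        + out_p.b_interaction * cum_a * cum_m
        + out_p.b_sg * (sg.mean(axis=1) - config.sg_mean)
        + out_cov
    )
    if out_p.intercept is None:
        b0 = float(
            brentq(lambda b: expit(b + eta).mean() - out_p.target_prevalence, -40.0, 10.0)
        )
    else:
        b0 = out_p.intercept
    expected_prev = float(expit(b0 + eta).mean())
    if expected_prev > config.rarity_ceiling:
        raise SimulationError(
            f"expected prevalence {expected_prev:.3f} exceeds the rarity ceiling "
            f"{config.rarity_ceiling:.2f}"
        )
    y = (rng.random(n) < expit(b0 + eta)).astype(int)

    # nested case-control subsample
    cases = np.flatnonzero(y == 1)
    noncases = np.flatnonzero(y == 0)
    if config.sampling is None:
        selected = np.arange(n)
        weights = np.ones(n)
    else:
        plan = config.sampling
        if len(cases) < plan.n_cases:
            raise InfeasibleSamplingError(
                f"requested {plan.n_cases} cases but only {len(cases)} realized "
                f"in a cohort of {n}"
            )
        if len(noncases) < plan.n_controls:
            raise InfeasibleSamplingError(
                f"requested {plan.n_controls} controls but only {len(noncases)} non-cases realized"
            )
        sel_cases = np.sort(rng.choice(cases, size=plan.n_cases, replace=False))
        sel_controls = np.sort(rng.choice(noncases, size=plan.n_controls, replace=False))
        selected = np.concatenate([sel_cases, sel_controls])
        order = np.argsort(selected)
        selected = selected[order]
        weights = np.where(
            y[selected] == 1,
            len(cases) / plan.n_cases,
            len(noncases) / plan.n_controls,
        )

    subjects = pd.DataFrame({"subject_id": selected, "outcome": y[selected], "weight": weights})
    subjects = pd.concat([subjects, cov.iloc[selected].reset_index(drop=True)], axis=1)

    # visit-level MCAR missingness; never remove all three visits
    ns = len(selected)
    u = rng.random((ns, N_VISITS))
    missing = u < np.asarray(config.missingness_rates)
    all_gone = missing.all(axis=1)
    if all_gone.any():
        keep_visit = np.argmin(u[all_gone], axis=1)
        missing[np.flatnonzero(all_gone), keep_visit] = False

    observed = ~missing
    rows = np.repeat(selected, N_VISITS).reshape(ns, N_VISITS)
    visit_idx = np.broadcast_to(np.array(VISITS), (ns, N_VISITS))
    visits = pd.DataFrame(
        {
            "subject_id": rows[observed],
            "visit": visit_idx[observed],
            "exposure": np.exp(a[selected])[observed],
            "mediator": np.exp(m[selected])[observed],
            "specific_gravity": sg[selected][observed],
        }
    )

    if out_p.b_interaction == 0.0:
        true_nde, true_nie = closed_form_truth(config)
    else:
        true_nde = true_nie = None
    truth = SimTruth(
        true_nde=true_nde,
        true_nie=true_nie,
        intercept=b0,
        expected_prevalence=expected_prev,
        realized_prevalence=float(y.mean()),
        source_cases=int(len(cases)),
        source_noncases=int(len(noncases)),
        config=config,
    )
    return CohortTable(subjects=subjects, visits=visits), truth


def true_effects_mc(
    config: SimConfig,
    scenario: LongScenario | None = None,
    intercept: float | None = None,
    n_draws: int = 1_000_000,
    seed: int = 12345,
) -> tuple[float, float, float, float]:
    """Ground-truth interventional NDE/NIE by brute-force g-formula.

    Evaluates the generating models exactly (no rare-outcome approximation)
    at fixed covariates -- reference categories, age at its generating mean
    and specific gravity at its mean, matching the estimators' covariate-
    fixing rule.  ``scenario`` defaults to a 1 ln-unit increase at every
    visit starting from the generating exposure means.  ``intercept`` must
    be supplied when the config solves it from a target prevalence (take it
    from :attr:`SimTruth.intercept`).

    Returns (nde, nie, nde_mc_se, nie_mc_se).
    """
    config.validate()
    if scenario is None:
        scenario = LongScenario(delta=(1.0, 1.0, 1.0), a_star_history=tuple(config.exposure.mean))
    b0 = config.outcome.intercept if config.outcome.intercept is not None else intercept
    if b0 is None:
        raise SimulationError(
            "outcome intercept unknown; pass intercept=SimTruth.intercept from a generated cohort"
        )
    med = config.mediator

    def means(history: tuple[float, ...]) -> np.ndarray:
        avg = np.cumsum(history) / np.arange(1, N_VISITS + 1)
        return np.asarray(med.intercept) + np.asarray(med.slope_exposure) * avg

    rng = np.random.default_rng(seed)
    return gformula_mc_core(
        outcome_intercept=b0,
        b_ya=config.outcome.b_cum_exposure,
        b_ym=config.outcome.b_cum_mediator,
        b_yi=config.outcome.b_interaction,
        outcome_offset=0.0,
        mediator_means_star=means(scenario.a_star_history),
        mediator_means_a=means(scenario.a_history),
        sigma2=med.sigma**2,
        corr=med.corr_matrix(),
        cum_a_star=float(np.sum(scenario.a_star_history)),
        cum_a=float(np.sum(scenario.a_history)),
        n_draws=n_draws,
        rng=rng,
    )
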