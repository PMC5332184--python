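"""End-to-end estimation pipeline: cohort table -> mediation effects.

This module wires the preprocessing, regression and effect layers together
and owns the small configuration vocabulary (which covariates enter the
models, reference levels, imputation strategy, whether outcome fits are
weighted).  The cohort is converted once into a wide numpy representation
(:class:`AnalysisData`) so the whole pipeline -- re-imputation,
re-standardization, model fits, effect computation -- can be re-run cheaply
on resampled subject indices inside the bootstrap.

Method map:

=======  ==========================  ==========================
method   outcome model               mediator model
=======  ==========================  ==========================
1        logit(Y) ~ Abar + Mbar      Mbar ~ Abar (IPW)
2        ... + Abar:Mbar             Mbar ~ Abar (IPW)
3        logit(Y) ~ cum(A) + cum(M)  M(t) ~ avg[A(t)], separate (IPW)
4        ... + cum(A):cum(M)         M(t) ~ avg[A(t)], joint FGLS (IPW)
=======  ==========================  ==========================

All models additionally adjust for the configured covariates and urinary
specific gravity (average in the outcome and average-mediator models,
visit-level in the per-visit mediator models).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects_average import MediationEffects, Scenario, effects_method1, effects_method2
from .effects_longitudinal import (
    LongScenario,
    effects_gformula_mc,
    effects_method3,
    effects_method4,
)
from .preprocess import (
    BIOMARKERS,
    CohortTable,
    N_VISITS,
    PreprocessingError,
    impute_wide,
)
from .regression import (
    DesignMatrix,
    fit_logistic_outcome,
    fit_mediator_average,
    fit_mediator_longitudinal,
)

METHODS = (1, 2, 3, 4)


class PipelineError(ValueError):
    pass


@dataclass
class CovariateSpec:
    """A covariate entering every model: continuous, or categorical with a
    declared reference level."""

    name: str
    kind: str = "continuous"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise PipelineError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise PipelineError(f"categorical covariate {self.name!r} needs a reference level")


#: covariate set of the emulated study: maternal age, race/ethnicity,
#: education, insurance and pre-pregnancy BMI category
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("age", "continuous"),
    CovariateSpec("race", "categorical", "white"),
    CovariateSpec("education", "categorical", "high_school"),
    CovariateSpec("insurance", "categorical", "private"),
    CovariateSpec("bmi_category", "categorical", "lt25"),
)


@dataclass
class AnalysisOptions:
    imputation: str = "subject_geomean"
    standardize: bool = True
    longitudinal_scope: str = "pooled"  # or "per_visit"
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    most_frequent_reference: bool = False
    weighted_outcome: bool = False
    rare_ceiling: float = 0.10


def build_covariates(
    subjects: pd.DataFrame,
    specs: tuple[CovariateSpec, ...] | list[CovariateSpec],
    most_frequent_reference: bool = False,
) -> tuple[np.ndarray, list[str], list[bool]]:
    """Encode covariates into a design block (no intercept).

    Categorical covariates become indicator contrasts against the declared
    reference level (or the modal level when ``most_frequent_reference`` is
    set, the sensitivity variant).  Returns the matrix, term names
    (``{covariate}_{level}`` for indicators) and a per-column continuous
    flag.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    continuous: list[bool] = []
    for spec in specs:
        if spec.name not in subjects.columns:
            raise PipelineError(f"covariate column {spec.name!r} not in subjects table")
        if spec.kind == "continuous":
            cols.append(subjects[spec.name].to_numpy(dtype=float))
            names.append(spec.name)
            continuous.append(True)
        else:
            values = subjects[spec.name].astype(str)
            levels = sorted(values.unique())
            reference = spec.reference
            if most_frequent_reference:
                reference = values.value_counts().idxmax()
            if reference not in levels:
                raise PipelineError(
                    f"reference level {reference!r} for {spec.name!r} not among "
                    f"observed categories {levels}"
                )
            for level in levels:
                if level == reference:
                    continue
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{spec.name}_{level}")
                continuous.append(False)
    X = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return X, names, continuous


@dataclass
class AnalysisData:
    """Wide numpy view of a cohort, the unit the bootstrap resamples."""

    a_log: np.ndarray  # (n, 3), NaN where missing
    m_log: np.ndarray
    sg: np.ndarray
    Xcov: np.ndarray  # (n, k) covariate block
    cov_names: list[str]
    cov_continuous: list[bool]
    y: np.ndarray
    weights: np.ndarray
    subject_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def case_mask(self) -> np.ndarray:
        return self.y == 1


def prepare(cohort: CohortTable, options: AnalysisOptions | None = None) -> AnalysisData:
    options = options or AnalysisOptions()
    with np.errstate(invalid="ignore"):
        a_log = np.log(cohort.wide("exposure"))
        m_log = np.log(cohort.wide("mediator"))
    for name, mat in zip(BIOMARKERS, (a_log, m_log)):
        if (~np.isnan(mat)).sum(axis=1).min() == 0:
            raise PipelineError(f"a subject has no observed {name} visits")
    Xcov, names, continuous = build_covariates(
        cohort.subjects, options.covariates, options.most_frequent_reference
    )
    return AnalysisData(
        a_log=a_log,
        m_log=m_log,
        sg=cohort.wide("specific_gravity"),
        Xcov=Xcov,
        cov_names=names,
        cov_continuous=continuous,
        y=cohort.subjects["outcome"].to_numpy(dtype=float),
        weights=cohort.subjects["weight"].to_numpy(dtype=float),
        subject_ids=cohort.subjects["subject_id"].to_numpy(),
    )


def _impute_block(
    a: np.ndarray, m: np.ndarray, sg: np.ndarray, strategy: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve missing visits inside a (re)sample; returns a keep-mask for
    complete-case mode."""
    keep = np.ones(len(a), dtype=bool)
    if strategy == "complete_case":
        keep = ~np.isnan(a).any(axis=1) & ~np.isnan(m).any(axis=1)
        return a[keep], m[keep], sg[keep], keep
    a, _ = impute_wide(a, strategy)
    m, _ = impute_wide(m, strategy)
    nan_sg = np.isnan(sg)
    if nan_sg.any():
        fill = (
            np.nanmean(sg, axis=1)[:, None]
            if strategy == "subject_geomean"
            else np.nanmean(sg, axis=0)[None, :]
        )
        sg = np.where(nan_sg, np.broadcast_to(fill, sg.shape), sg)
    return a, m, sg, keep


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    # relative floor also catches columns constant up to rounding noise
    if sd <= 1e-10 * max(1.0, abs(mean)) or not np.isfinite(sd):
        raise PreprocessingError(f"zero-variance {name}; cannot standardize")
    return (values - mean) / sd


def _fixed_covariates(Xcov: np.ndarray, names: list[str], continuous: list[bool]) -> dict[str, float]:
    """Covariate-fixing rule: continuous at the arithmetic mean, indicator
    terms at 0 (the reference level)."""
    fixed: dict[str, float] = {}
    for j, (name, cont) in enumerate(zip(names, continuous)):
        fixed[name] = float(Xcov[:, j].mean()) if cont else 0.0
    return fixed


def estimate(
    data: AnalysisData,
    method: int,
    options: AnalysisOptions | None = None,
    scenario: Scenario | LongScenario | None = None,
    indices: np.ndarray | None = None,
    return_fits: bool = False,
) -> MediationEffects:
    """Point estimate of the mediation effects for one method.

    ``indices`` selects (possibly repeated) subjects, which makes this the
    replicate kernel of the bootstrap: imputation, standardization and the
    covariate-fixing rule are all recomputed on the selected sample.
    With ``return_fits`` the underlying (outcome, mediator) model fits are
    returned alongside the effects, for auditing.
    """
    if method not in METHODS:
        raise PipelineError(f"method must be one of {METHODS}")
    options = options or AnalysisOptions()
    idx = np.arange(data.n) if indices is None else np.asarray(indices)

    a, m, sg = data.a_log[idx], data.m_log[idx], data.sg[idx]
    Xcov, y, w = data.Xcov[idx], data.y[idx], data.weights[idx]
    a, m, sg, keep = _impute_block(a, m, sg, options.imputation)
    if not keep.all():
        Xcov, y, w = Xcov[keep], y[keep], w[keep]
    if len(y) == 0 or y.min() == y.max():
        raise PipelineError("sample has no outcome variation after imputation/selection")

    # center specific gravity (values ~1.01 with tiny spread would otherwise
    # make the design nearly collinear with the intercept); covariate fixing
    # then pins it at 0, i.e. its sample mean
    sg = sg - sg.mean(axis=0)
    lbar = sg.mean(axis=1)
    prevalence = float(np.sum(w * y) / np.sum(w))
    fixed = _fixed_covariates(Xcov, data.cov_names, data.cov_continuous)
    outcome_weights = w if options.weighted_outcome else None

    if method in (1, 2):
        abar, mbar = a.mean(axis=1), m.mean(axis=1)
        if options.standardize:
            abar, mbar = _zscore(abar, "exposure average"), _zscore(mbar, "mediator average")
        base = [np.ones(len(y)), abar, mbar]
        names = ["intercept", "exposure", "mediator"]
        if method == 2:
            base.append(abar * mbar)
            names.append("exposure:mediator")
        X_out = np.column_stack(base + [Xcov, lbar[:, None]])
        out_design = DesignMatrix(X_out, names + data.cov_names + ["specific_gravity"])
        outcome_fit = fit_logistic_outcome(out_design, y, outcome_weights)
        med_design = DesignMatrix(
            np.column_stack([np.ones(len(y)), abar[:, None], Xcov, lbar[:, None]]),
            ["intercept", "exposure"] + data.cov_names + ["specific_gravity"],
        )
        mediator_fit = fit_mediator_average(med_design, mbar, w)
        scen = scenario or Scenario()
        if not scen.fixed_covariates:
            scen = replace(
                scen, fixed_covariates={**fixed, "specific_gravity": 0.0}
            )
        fn = effects_method1 if method == 1 else effects_method2
        eff = fn(outcome_fit, mediator_fit, scen, prevalence, options.rare_ceiling)
        return (eff, (outcome_fit, mediator_fit)) if return_fits else eff

    # longitudinal methods
    if options.standardize:
        if options.longitudinal_scope == "pooled":
            a = (a - a.mean()) / a.std(ddof=1)
            m = (m - m.mean()) / m.std(ddof=1)
        else:
            a = np.column_stack([_zscore(a[:, t], f"exposure visit {t + 1}") for t in range(N_VISITS)])
            m = np.column_stack([_zscore(m[:, t], f"mediator visit {t + 1}") for t in range(N_VISITS)])
    cum_a, cum_m = a.sum(axis=1), m.sum(axis=1)
    base = [np.ones(len(y)), cum_a, cum_m]
    names = ["intercept", "cum_exposure", "cum_mediator"]
    if method == 4:
        base.append(cum_a * cum_m)
        names.append("cum_exposure:cum_mediator")
    X_out = np.column_stack(base + [Xcov, lbar[:, None]])
    out_design = DesignMatrix(X_out, names + data.cov_names + ["specific_gravity"])
    outcome_fit = fit_logistic_outcome(out_design, y, outcome_weights)

    avg_a = np.cumsum(a, axis=1) / np.arange(1, N_VISITS + 1)
    designs = [
        DesignMatrix(
            np.column_stack([np.ones(len(y)), avg_a[:, t : t + 1], Xcov, sg[:, t : t + 1]]),
            ["intercept", "exposure_avg"] + data.cov_names + ["specific_gravity"],
        )
        for t in range(N_VISITS)
    ]
    mediator_fits = fit_mediator_longitudinal(designs, m, w, joint=(method == 4))
    scen = scenario or LongScenario()
    if not scen.fixed_covariates:
        scen = replace(
            scen,
            fixed_covariates=fixed,
            fixed_specific_gravity=0.0,
        )
    fn = effects_method3 if method == 3 else effects_method4
    eff = fn(outcome_fit, mediator_fits, scen, prevalence, options.rare_ceiling)
    return (eff, (outcome_fit, mediator_fits)) if return_fits else eff


def analyze(
    cohort: CohortTable,
    method: int,
    options: AnalysisOptions | None = None,
    scenario: Scenario | LongScenario | None = None,
    bootstrap=None,
) -> MediationEffects:
    """Run one mediation method on a cohort, optionally with bootstrap CIs.

    ``bootstrap`` is a :class:`longmediate.inference.BootstrapConfig`; when
    given, the whole pipeline is re-run per replicate (stratified subject
    resampling) and percentile intervals are attached to the result.
    """
    options = options or AnalysisOptions()
    data = prepare(cohort, options)
    if bootstrap is None:
        return estimate(data, method, options, scenario)
    from .inference import bootstrap_effects

    return bootstrap_effects(
        data.case_mask,
        lambda idx: estimate(data, method, options, scenario, indices=idx),
        bootstrap,
    )


def crosscheck_mc(
    cohort: CohortTable,
    options: AnalysisOptions | None = None,
    scenario: LongScenario | None = None,
    n_draws: int = 200_000,
    seed: int = 0,
) -> tuple[MediationEffects, dict[str, float]]:
    """Monte-Carlo g-formula evaluation of the Method 4 contrasts.

    Re-fits the Method 4 models and evaluates the interventional effects by
    drawing mediator vectors from the fitted multivariate normal instead of
    using the closed forms (cross-check oracle).
    """
    options = options or AnalysisOptions()
    data = prepare(cohort, options)
    # re-run the method-4 fitting path explicitly, then hand the fits to the
    # MC evaluator; small duplication keeps estimate() lean for the bootstrap
    idx = np.arange(data.n)
    a, m, sg = data.a_log[idx], data.m_log[idx], data.sg[idx]
    Xcov, y, w = data.Xcov, data.y, data.weights
    a, m, sg, keep = _impute_block(a, m, sg, options.imputation)
    Xcov, y, w = Xcov[keep], y[keep], w[keep]
    if options.standardize:
        a = (a - a.mean()) / a.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
    sg = sg - sg.mean(axis=0)
    lbar = sg.mean(axis=1)
    cum_a, cum_m = a.sum(axis=1), m.sum(axis=1)
    out_design = DesignMatrix(
        np.column_stack([np.ones(len(y)), cum_a, cum_m, cum_a * cum_m, Xcov, lbar[:, None]]),
        ["intercept", "cum_exposure", "cum_mediator", "cum_exposure:cum_mediator"]
        + data.cov_names
        + ["specific_gravity"],
    )
    outcome_fit = fit_logistic_outcome(out_design, y)
    avg_a = np.cumsum(a, axis=1) / np.arange(1, N_VISITS + 1)
    designs = [
        DesignMatrix(
            np.column_stack([np.ones(len(y)), avg_a[:, t : t + 1], Xcov, sg[:, t : t + 1]]),
            ["intercept", "exposure_avg"] + data.cov_names + ["specific_gravity"],
        )
        for t in range(N_VISITS)
    ]
    mediator_fits = fit_mediator_longitudinal(designs, m, w, joint=True)
    scen = scenario or LongScenario()
    if not scen.fixed_covariates:
        scen = replace(
            scen,
            fixed_covariates=_fixed_covariates(Xcov, data.cov_names, data.cov_continuous),
            fixed_specific_gravity=0.0,
        )
    return effects_gformula_mc(
        outcome_fit, mediator_fits, scen, n_draws=n_draws, rng=np.random.default_rng(seed)
    )
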