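"""Weighted regression layer: the eight working models behind the four
mediation estimators.

Outcome models are logistic regressions fit by iteratively reweighted least
squares (IRLS); mediator models are (inverse-probability-)weighted least
squares, either on subject averages, per visit, or jointly across the three
visits with multivariate-normal errors sharing a common variance and an
unstructured correlation matrix with unit diagonal (a seemingly-unrelated-
regressions system fit by iterated feasible GLS).

Outcome models default to unweighted fitting on the case-control sample:
with a rare outcome the sampling biases only the intercept, and every
direct/indirect-effect expression downstream uses slopes only.  The mediator
models are always weighted by the case-control inverse probability weights.
All interval estimation is delegated to the subject-level bootstrap; the
model-based covariances kept on each fit serve only as rough scale
references (e.g. for simulation tolerances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.special import expit

FGLS_TOL = 1e-8
FGLS_MAX_ITER = 50
IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100


class ConvergenceError(RuntimeError):
    """IRLS or FGLS failed to converge (e.g. separated data)."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass
class DesignMatrix:
    """A dense design matrix with named columns (intercept included)."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design shape does not match term names")


@dataclass
class ModelFit:
    """Fitted coefficients plus the auxiliary quantities mediation needs.

    ``terms``/``params``/``cov`` describe the stacked coefficient vector;
    for the longitudinal mediator system terms are suffixed ``@t1..@t3``.
    ``sigma2`` is the residual variance of a mediator model, ``corr`` the
    3x3 residual correlation of the joint system, and ``var_cum_m`` the
    implied variance of M(1)+M(2)+M(3), sigma2 * 1' corr 1.
    """

    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    n: int
    weighted: bool
    sigma2: float | None = None
    sigma2_by_visit: np.ndarray | None = None
    corr: np.ndarray | None = None
    var_cum_m: float | None = None
    converged: bool = True
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    def coef(self, name: str, default: float | None = None) -> float:
        if name in self.terms:
            return float(self.params[self.terms.index(name)])
        if default is None:
            raise KeyError(f"term {name!r} not in fit ({self.terms})")
        return default

    def has_term(self, name: str) -> bool:
        return name in self.terms

    def se(self, name: str) -> float:
        i = self.terms.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.terms, map(float, self.params)))

    def visit_coef(self, name: str, t: int) -> float:
        return self.coef(f"{name}@t{t}")


# ---------------------------------------------------------------------------
# inverse probability weights for the nested case-control design
# ---------------------------------------------------------------------------


def compute_ipw(
    outcome: np.ndarray,
    source_noncases: int | None,
    source_cases: int | None = None,
) -> np.ndarray:
    """Per-subject sampling weights for a nested case-control sample.

    Cases carry weight 1 (all cases sampled, the usual nested design);
    controls carry (non-cases in the source cohort) / (controls sampled).
    Supplying ``source_cases`` generalises to subsampled cases.
    """
    y = np.asarray(outcome)
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if source_noncases is None:
        raise ValueError(
            "source cohort non-case count is required for IPW; supply it or "
            "run the unweighted sensitivity mode explicitly"
        )
    if source_noncases < n_controls:
        raise ValueError("controls sampled exceed source-cohort non-cases")
    if n_controls == 0:
        raise ValueError("no controls in sample")
    w = np.ones(len(y), dtype=float)
    w[y == 0] = source_noncases / n_controls
    if source_cases is not None:
        if source_cases < n_cases:
            raise ValueError("cases sampled exceed source-cohort cases")
        w[y == 1] = source_cases / n_cases
    return w


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(f"design matrix rank deficient; collinear terms: {bad}")


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares; returns (beta, cov, sigma2).

    sigma2 is the weight-normalised residual variance with a small-sample
    degrees-of-freedom correction n/(n-p).
    """
    n, p = X.shape
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    e = y - X @ beta
    wsum = w.sum()
    sigma2 = float(np.sum(w * e**2) / wsum * (n / max(n - p, 1)))
    XtWX = X.T @ (X * w[:, None])
    cov = sigma2 * np.linalg.inv(XtWX)
    return beta, cov, sigma2


# ---------------------------------------------------------------------------
# outcome models (Models 1, 3, 5, 7)
# ---------------------------------------------------------------------------


def fit_logistic_outcome(
    design: DesignMatrix,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = IRLS_MAX_ITER,
    tol: float = IRLS_TOL,
) -> ModelFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``weights`` are sampling (frequency-type) weights; by default the fit is
    unweighted (see module docstring).  Raises :class:`ConvergenceError`
    with the iteration trace on separation or non-convergence, and
    :class:`RankDeficiencyError` naming collinear terms.
    """
    X, names = design.X, design.names
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    _check_rank(X * np.sqrt(w)[:, None], names)

    def deviance(b: np.ndarray) -> float:
        eta = X @ b
        # log-likelihood of Bernoulli with logit link, numerically stable
        return float(2.0 * np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

    beta = np.zeros(X.shape[1])
    dev = deviance(beta)
    trace: list[tuple[int, float]] = []
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        s = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / s
        sw = w * s
        XtWX = X.T @ (X * sw[:, None])
        XtWz = X.T @ (sw * z)
        try:
            # rank was checked up front; np.linalg.solve avoids spurious
            # conditioning warnings on transient IRLS weight patterns
            beta_new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ConvergenceError(f"IRLS normal equations singular at iter {it}", trace) from exc
        # step-halving keeps oscillating fits on the likelihood ascent path
        dev_new = deviance(beta_new)
        for _ in range(20):
            if dev_new <= dev + 1e-10 or not np.isfinite(dev_new):
                break
            beta_new = 0.5 * (beta_new + beta)
            dev_new = deviance(beta_new)
        delta = float(np.max(np.abs(beta_new - beta)))
        trace.append((it, delta))
        beta, dev = beta_new, dev_new
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            raise ConvergenceError(
                "IRLS diverged (possible complete separation); "
                f"max |coef| = {np.max(np.abs(beta)):.3g} at iter {it}",
                trace,
            )
        if delta < tol * (1.0 + float(np.max(np.abs(beta)))):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (last step {trace[-1][1]:.3g}); "
            "check for separation",
            trace,
        )
    mu = expit(X @ beta)
    s = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * (w * s)[:, None]))
    return ModelFit(
        terms=list(names),
        params=beta,
        cov=cov,
        n=len(y),
        weighted=weights is not None,
        converged=True,
        n_iter=len(trace),
    )


# ---------------------------------------------------------------------------
# average-based mediator model (Models 2, 4)
# ---------------------------------------------------------------------------


def fit_mediator_average(
    design: DesignMatrix,
    mbar: np.ndarray,
    weights: np.ndarray,
) -> ModelFit:
    """IPW linear regression of the subject-average log mediator.

    The mediator models are always weighted for the case-control design;
    pass unit weights to recover ordinary least squares.
    """
    X, names = design.X, design.names
    mbar = np.asarray(mbar, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != mbar.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match the outcome length")
    _check_rank(X * np.sqrt(w)[:, None], names)
    beta, cov, sigma2 = _wls(X, mbar, w)
    fit = ModelFit(
        terms=list(names),
        params=beta,
        cov=cov,
        n=len(mbar),
        weighted=True,
        sigma2=sigma2,
    )
    if sigma2 <= np.finfo(float).eps * max(1.0, float(np.var(mbar))):
        fit.warnings.append("degenerate fit: residual variance is (numerically) zero")
    return fit


# ---------------------------------------------------------------------------
# longitudinal mediator system (Models 6, 8)
# ---------------------------------------------------------------------------


def fit_mediator_longitudinal(
    designs: list[DesignMatrix],
    M: np.ndarray,
    weights: np.ndarray,
    joint: bool = False,
    fixed_corr: np.ndarray | None = None,
    max_iter: int = FGLS_MAX_ITER,
    tol: float = FGLS_TOL,
) -> ModelFit:
    """Fit the three visit-level mediator regressions.

    ``designs`` holds one design matrix per visit (regressor of interest is
    the running exposure average avg[a(t)]); ``M`` is the (n, 3) matrix of
    log mediator values (no missing entries: impute first).

    joint=False
        three separate IPW least-squares fits, coefficients suffixed
        ``@t1..@t3`` (visit-specific coefficients).
    joint=True
        iterated feasible GLS across the stacked system assuming errors
        eps ~ MVN(0, sigma2 * Sigma) with common variance and unstructured
        unit-diagonal correlation; also reports the implied
        Var(M(1)+M(2)+M(3)) = sigma2 * 1' Sigma 1.

    ``fixed_corr`` pins Sigma instead of estimating it (identity reproduces
    the separate fits).
    """
    M = np.asarray(M, dtype=float)
    n, T = M.shape
    if len(designs) != T:
        raise ValueError(f"expected {T} visit designs, got {len(designs)}")
    if np.isnan(M).any():
        raise ValueError("missing mediator values; impute before fitting")
    w = np.asarray(weights, dtype=float)
    terms: list[str] = []
    for t, d in enumerate(designs, start=1):
        _check_rank(d.X * np.sqrt(w)[:, None], d.names)
        terms += [f"{name}@t{t}" for name in d.names]
    sizes = [d.X.shape[1] for d in designs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    p_tot = int(offsets[-1])

    def separate() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        beta = np.empty(p_tot)
        cov = np.zeros((p_tot, p_tot))
        s2 = np.empty(T)
        for t in range(T):
            b, c, sig2 = _wls(designs[t].X, M[:, t], w)
            sl = slice(offsets[t], offsets[t + 1])
            beta[sl] = b
            cov[sl, sl] = c
            s2[t] = sig2
        return beta, cov, s2

    if not joint:
        beta, cov, s2 = separate()
        return ModelFit(
            terms=terms,
            params=beta,
            cov=cov,
            n=n,
            weighted=True,
            sigma2=float(s2.mean()),
            sigma2_by_visit=s2,
        )

    # iterated FGLS with common sigma^2 and unit-diagonal correlation
    beta, _, s2 = separate()  # OLS start
    corr = np.eye(T) if fixed_corr is None else np.asarray(fixed_corr, dtype=float)
    wsum = w.sum()
    dof = n / max(n - max(sizes), 1)
    sigma2 = float(s2.mean())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resid = np.column_stack(
            [M[:, t] - designs[t].X @ beta[offsets[t] : offsets[t + 1]] for t in range(T)]
        )
        C = (resid * w[:, None]).T @ resid / wsum * dof
        sigma2 = float(np.mean(np.diag(C)))
        if fixed_corr is None:
            d = np.sqrt(np.diag(C))
            corr = C / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
        if np.min(np.linalg.eigvalsh(corr)) <= 0:
            raise ConvergenceError("estimated residual correlation not positive definite")
        omega_inv = np.linalg.inv(corr)
        A = np.zeros((p_tot, p_tot))
        b_vec = np.zeros(p_tot)
        for t in range(T):
            st = slice(offsets[t], offsets[t + 1])
            for s in range(T):
                ss = slice(offsets[s], offsets[s + 1])
                A[st, ss] += omega_inv[t, s] * (designs[t].X.T @ (designs[s].X * w[:, None]))
            b_vec[st] += designs[t].X.T @ (w * (M @ omega_inv[t]))
        beta_new = np.linalg.solve(A, b_vec)
        delta = float(np.max(np.abs(beta_new - beta))) / (1.0 + float(np.max(np.abs(beta_new))))
        beta = beta_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"FGLS did not converge in {max_iter} iterations; last correlation:\n{corr}"
        )
    cov = np.linalg.inv(A) * sigma2
    ones = np.ones(T)
    return ModelFit(
        terms=terms,
        params=beta,
        cov=cov,
        n=n,
        weighted=True,
        sigma2=sigma2,
        corr=corr,
        var_cum_m=float(sigma2 * ones @ corr @ ones),
        n_iter=n_iter,
    )
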