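"""Bootstrap inference and report tables.

Standard errors and confidence intervals for all four mediation methods
come from a subject-level nonparametric bootstrap, stratified by case
status so every replicate keeps the original case and control counts (the
case-control design is part of the sampling scheme, so it is preserved
under resampling).  The whole estimation pipeline -- single imputation,
standardization, model fits, effect computation -- is re-run inside every
replicate, so imputation and scaling uncertainty propagate into the
intervals.  Intervals are percentile-based, which is robust for the
skewed ratio-derived quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .effects_average import MediationEffects

logger = logging.getLogger("longmediate")


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapConfig:
    """Subject-resampling plan.

    ``seed`` feeds a SeedSequence that spawns one independent stream per
    replicate, so results are reproducible and order-independent.
    Replicates whose pipeline fails (e.g. a separated refit) are dropped
    and logged, up to ``max_failure_frac`` of ``n_reps``; beyond that the
    bootstrap aborts.
    """

    n_reps: int = 1000
    stratified: bool = True
    seed: int = 0
    ci_level: float = 0.95
    ci_method: str = "percentile"
    max_failure_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reps < 0 or (0 < self.n_reps < 2):
            raise ValueError("n_reps must be 0 (point estimates only) or >= 2")
        if self.ci_method != "percentile":
            raise ValueError("only percentile intervals are implemented")


def _resample(
    rng: np.random.Generator, case_idx: np.ndarray, control_idx: np.ndarray, stratified: bool
) -> np.ndarray:
    if stratified:
        return np.concatenate(
            [
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(control_idx, size=len(control_idx), replace=True),
            ]
        )
    pool = np.concatenate([case_idx, control_idx])
    return rng.choice(pool, size=len(pool), replace=True)


def bootstrap_effects(
    case_mask: np.ndarray,
    estimate: Callable[[np.ndarray], MediationEffects],
    config: BootstrapConfig | None = None,
) -> MediationEffects:
    """Percentile bootstrap CIs around ``estimate(all subjects)``.

    ``estimate`` maps an array of subject indices (with repeats) to a
    :class:`MediationEffects`; it must re-run the full pipeline on that
    sample.  The returned effects carry the point estimates with a ``ci``
    dict for nde / nie / total plus a descriptive percent-mediated interval
    computed from the replicate ratios.
    """
    config = config or BootstrapConfig()
    case_mask = np.asarray(case_mask, dtype=bool)
    n = len(case_mask)
    point = estimate(np.arange(n))
    if config.n_reps == 0:
        return point

    case_idx = np.flatnonzero(case_mask)
    control_idx = np.flatnonzero(~case_mask)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    reps = np.full((config.n_reps, 3), np.nan)  # nde, nie, total
    percents = np.full(config.n_reps, np.nan)
    failures = 0
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        idx = _resample(rng, case_idx, control_idx, config.stratified)
        try:
            eff = estimate(idx)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            continue
        reps[r] = (eff.nde, eff.nie, eff.total)
        percents[r] = 100.0 * eff.nie / eff.total if eff.total != 0 else np.nan

    allowed = max(1, int(np.floor(config.max_failure_frac * config.n_reps)))
    if failures > allowed:
        raise BootstrapError(
            f"{failures} of {config.n_reps} bootstrap replicates failed "
            f"(tolerance {allowed}); inspect the log"
        )
    ok = ~np.isnan(reps[:, 0])
    alpha = 100.0 * (1.0 - config.ci_level) / 2.0
    lo, hi = alpha, 100.0 - alpha
    ci = {
        name: tuple(float(q) for q in np.percentile(reps[ok, j], [lo, hi]))
        for j, name in enumerate(("nde", "nie", "total"))
    }
    pm = percents[ok]
    pm = pm[np.isfinite(pm)]
    if pm.size:
        # descriptive only: a ratio of resampled quantities, not a pivotal CI
        ci["percent_mediated_descriptive"] = tuple(float(q) for q in np.percentile(pm, [lo, hi]))
    return point.with_ci(ci, n_boot=int(ok.sum()))


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def _fmt_ci(value: float, ci: tuple[float, float] | None, digits: int = 3) -> str:
    if ci is None:
        return f"{value:.{digits}f} (NA, NA)"
    return f"{value:.{digits}f} ({ci[0]:.{digits}f}, {ci[1]:.{digits}f})"


def summarize_table(
    effects: Sequence[MediationEffects],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per analysis: NDE (CI), NIE (CI), TE (CI), percent mediated.

    Mirrors the standard mediation-report layout; the percent-mediated
    column is rounded to the nearest integer (``NA`` when direct and
    indirect effects oppose each other), and the NIE CI width is included
    to support precision comparisons across methods.
    """
    if not effects:
        raise ValueError("need at least one effect estimate")
    labels = list(labels) if labels is not None else [f"analysis_{i}" for i in range(len(effects))]
    rows = []
    for label, eff in zip(labels, effects):
        nie_ci = eff.ci.get("nie")
        rows.append(
            {
                "label": label,
                "method": eff.method,
                "nde": eff.nde,
                "nde_95ci": _fmt_ci(eff.nde, eff.ci.get("nde")),
                "nie": eff.nie,
                "nie_95ci": _fmt_ci(eff.nie, nie_ci),
                "total": eff.total,
                "total_95ci": _fmt_ci(eff.total, eff.ci.get("total")),
                "percent_mediated": eff.percent_rounded if eff.percent_interpretable else pd.NA,
                "nie_ci_width": (nie_ci[1] - nie_ci[0]) if nie_ci else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def compare_methods(table: pd.DataFrame, baseline_method: int = 1) -> pd.DataFrame:
    """Cross-method comparison of percent mediated and NIE CI width.

    ``table`` is a :func:`summarize_table` output whose labels encode the
    channel; widths are differenced against ``baseline_method`` per label.
    """
    out = table.copy()
    base = table[table["method"] == baseline_method].set_index("label")["nie_ci_width"]
    out["nie_ci_width_vs_baseline"] = [
        (row.nie_ci_width - base[row.label])
        if row.label in base.index and pd.notna(row.nie_ci_width) and pd.notna(base[row.label])
        else pd.NA
        for row in table.itertuples()
    ]
    return out
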