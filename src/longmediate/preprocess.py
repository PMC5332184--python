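"""Cohort container and biomarker preprocessing.

Raw urinary biomarker concentrations arrive in long format (one row per
subject-visit) together with a subject-level table of time-invariant
covariates, the binary outcome and the case-control sampling weight.  The
analysis works on natural-log concentrations, optionally z-scored; visits
missing a biomarker are singly imputed before modelling.

Missing visits may be encoded either as absent rows or as NaN entries in the
``exposure`` / ``mediator`` columns; both are treated identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

VISITS = (1, 2, 3)
N_VISITS = 3

#: columns every visit-level table must carry
VISIT_COLUMNS = ("subject_id", "visit", "exposure", "mediator", "specific_gravity")
#: columns every subject-level table must carry (covariates come in addition)
SUBJECT_COLUMNS = ("subject_id", "outcome", "weight")

BIOMARKERS = ("exposure", "mediator")

IMPUTATION_STRATEGIES = ("subject_geomean", "complete_case", "population_mean")


class PreprocessingError(ValueError):
    """Raised for invalid concentrations, strategies or degenerate inputs."""


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Tidy case-control cohort: subject-level and visit-level tables.

    Parameters
    ----------
    subjects
        One row per subject with ``subject_id``, binary ``outcome``,
        sampling ``weight`` and any covariate columns.
    visits
        One row per observed subject-visit with ``subject_id``, ``visit``
        in {1, 2, 3}, ``exposure`` and ``mediator`` concentrations and
        ``specific_gravity``.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        for col in SUBJECT_COLUMNS:
            if col not in self.subjects.columns:
                raise PreprocessingError(f"subjects table missing column {col!r}")
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise PreprocessingError(f"visits table missing column {col!r}")
        if self.subjects["subject_id"].duplicated().any():
            raise PreprocessingError("duplicate subject_id in subjects table")
        if self.visits.duplicated(["subject_id", "visit"]).any():
            raise PreprocessingError("duplicate (subject_id, visit) in visits table")
        if not self.visits["visit"].isin(VISITS).all():
            raise PreprocessingError("visit index outside {1, 2, 3}")
        for col in BIOMARKERS:
            vals = self.visits[col].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise PreprocessingError(f"non-positive {col} concentration")
        outcome = self.subjects["outcome"].to_numpy()
        if not np.isin(outcome, (0, 1)).all():
            raise PreprocessingError("outcome must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def covariate_columns(self) -> list[str]:
        return [c for c in self.subjects.columns if c not in SUBJECT_COLUMNS]

    # -- wide helpers -------------------------------------------------------

    def wide(self, column: str) -> np.ndarray:
        """Return an ``(n_subjects, 3)`` array of ``column`` with NaN for
        missing visits, rows aligned with ``self.subjects``."""
        piv = self.visits.pivot(index="subject_id", columns="visit", values=column)
        piv = piv.reindex(index=self.subjects["subject_id"], columns=list(VISITS))
        return piv.to_numpy(dtype=float)

    # -- persistence --------------------------------------------------------

    def to_csv(self, directory: str | Path, prefix: str = "cohort") -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        subj = directory / f"{prefix}_subjects.csv"
        vis = directory / f"{prefix}_visits.csv"
        self.subjects.to_csv(subj, index=False)
        self.visits.to_csv(vis, index=False)
        return subj, vis

    @classmethod
    def from_csv(cls, subjects_path: str | Path, visits_path: str | Path) -> "CohortTable":
        return cls(
            subjects=pd.read_csv(subjects_path),
            visits=pd.read_csv(visits_path),
        )


# ---------------------------------------------------------------------------
# below-LOD substitution
# ---------------------------------------------------------------------------


def substitute_lod(
    values: pd.Series | np.ndarray | Iterable[float],
    lod: float,
    nondetect: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Replace non-detected concentrations by LOD / sqrt(2).

    ``nondetect`` flags machine non-detects explicitly; when omitted, values
    strictly below ``lod`` (or NaN) are taken as non-detects.  Detected
    values pass through unchanged, even if the laboratory reported a value
    below the nominal LOD.
    """
    if lod <= 0:
        raise PreprocessingError("lod must be positive")
    vals = pd.Series(values, dtype=float).copy()
    finite = vals.notna()
    if (vals[finite] < 0).any():
        raise PreprocessingError("negative concentration in input")
    if nondetect is None:
        mask = vals.isna() | (vals < lod)
    else:
        mask = pd.Series(np.asarray(nondetect, dtype=bool), index=vals.index)
    vals[mask] = lod / np.sqrt(2.0)
    return vals


# ---------------------------------------------------------------------------
# missing-visit imputation
# ---------------------------------------------------------------------------


def impute_wide(
    logmat: np.ndarray,
    strategy: str,
    subject_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing entries of an (n, 3) log-concentration matrix.

    Returns ``(filled, flags)`` where ``flags`` marks imputed cells.  The
    geometric mean of concentrations equals the arithmetic mean of logs, so
    both single-imputation strategies operate directly on the log scale.
    ``complete_case`` is handled at the table level (it drops subjects, it
    does not fill).
    """
    if strategy not in ("subject_geomean", "population_mean"):
        raise PreprocessingError(f"unknown imputation strategy {strategy!r}")
    logmat = np.asarray(logmat, dtype=float)
    flags = np.isnan(logmat)
    if not flags.any():
        return logmat.copy(), flags
    filled = logmat.copy()
    if strategy == "subject_geomean":
        n_obs = (~flags).sum(axis=1)
        if (n_obs == 0).any():
            bad = np.where(n_obs == 0)[0]
            ids = bad if subject_ids is None else np.asarray(subject_ids)[bad]
            raise PreprocessingError(
                f"subject(s) with no observed visits under subject_geomean: {list(ids)}"
            )
        with np.errstate(invalid="ignore"):
            subj_mean = np.nanmean(logmat, axis=1)
        rows, cols = np.where(flags)
        filled[rows, cols] = subj_mean[rows]
    else:  # population_mean
        n_obs = (~flags).sum(axis=0)
        if (n_obs == 0).any():
            raise PreprocessingError("a visit has no observed values; cannot take population mean")
        visit_mean = np.nanmean(logmat, axis=0)
        rows, cols = np.where(flags)
        filled[rows, cols] = visit_mean[cols]
    return filled, flags


def impute_missing(table: CohortTable, strategy: str) -> CohortTable:
    """Resolve missing biomarker visits according to ``strategy``.

    subject_geomean
        fill a missing visit with the geometric mean of that subject's
        observed visits (the default single-imputation rule);
    complete_case
        drop every subject missing any exposure or mediator visit;
    population_mean
        fill with the geometric mean over all observed subjects at that
        visit (sensitivity variant).

    Imputed tables carry ``exposure_imputed`` / ``mediator_imputed`` flag
    columns and exactly three visit rows per subject.  Specific gravity on
    an absent visit row is filled with the subject (or visit) arithmetic
    mean, since it is a covariate rather than a concentration.
    """
    if strategy not in IMPUTATION_STRATEGIES:
        raise PreprocessingError(f"unknown imputation strategy {strategy!r}")
    ids = table.subjects["subject_id"].to_numpy()
    wide = {col: table.wide(col) for col in ("exposure", "mediator", "specific_gravity")}

    if strategy == "complete_case":
        complete = ~np.isnan(wide["exposure"]).any(axis=1) & ~np.isnan(wide["mediator"]).any(axis=1)
        keep = set(ids[complete])
        subjects = table.subjects[table.subjects["subject_id"].isin(keep)].reset_index(drop=True)
        visits = table.visits[table.visits["subject_id"].isin(keep)].reset_index(drop=True)
        visits = visits.assign(exposure_imputed=False, mediator_imputed=False)
        return CohortTable(subjects=subjects, visits=visits)

    out: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for col in BIOMARKERS:
        with np.errstate(invalid="ignore"):
            logmat = np.log(wide[col])
        filled, flag = impute_wide(logmat, strategy, subject_ids=ids)
        out[col] = np.exp(filled)
        flags[col] = flag
    sg = wide["specific_gravity"]
    sg_flag = np.isnan(sg)
    if sg_flag.any():
        if strategy == "subject_geomean":
            fill = np.nanmean(sg, axis=1)[:, None]
        else:
            fill = np.nanmean(sg, axis=0)[None, :]
        sg = np.where(sg_flag, np.broadcast_to(fill, sg.shape), sg)

    long = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, N_VISITS),
            "visit": np.tile(np.array(VISITS), len(ids)),
            "exposure": out["exposure"].ravel(),
            "mediator": out["mediator"].ravel(),
            "specific_gravity": sg.ravel(),
            "exposure_imputed": flags["exposure"].ravel(),
            "mediator_imputed": flags["mediator"].ravel(),
        }
    )
    return CohortTable(subjects=table.subjects.reset_index(drop=True), visits=long)


# ---------------------------------------------------------------------------
# log transform and standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationSpec:
    """Constants used to z-score log concentrations, kept for inversion.

    ``scope`` is ``"average"`` (subject-mean logs standardized, for the
    average-based methods) or ``"pooled"`` (visit-level logs standardized
    with one pooled mean/SD per biomarker, so a 1-SD contrast means the same
    thing at every visit) or ``"per_visit"``.
    """

    scope: str
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, name: str, log_values: np.ndarray) -> np.ndarray:
        return (np.asarray(log_values, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z_values: np.ndarray) -> np.ndarray:
        return np.asarray(z_values, dtype=float) * self.sds[name] + self.means[name]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"scope": self.scope, "means": self.means, "sds": self.sds}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationSpec":
        d = json.loads(Path(path).read_text())
        return cls(scope=d["scope"], means=d["means"], sds=d["sds"])


def _standardize(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    # relative floor also catches columns constant up to rounding noise
    if sd <= 1e-10 * max(1.0, abs(mean)) or not np.isfinite(sd):
        raise PreprocessingError(f"zero-variance variable {name!r}; cannot standardize")
    return (values - mean) / sd, mean, sd


def log_standardize(
    table: CohortTable,
    scope: str = "average",
    spec: StandardizationSpec | None = None,
) -> tuple[CohortTable, StandardizationSpec]:
    """Log-transform exposure and mediator and z-score them.

    With ``scope="average"`` the subject averages of log concentrations are
    standardized and written to the subjects table as ``exposure_avg_std``
    and ``mediator_avg_std`` (plus raw ``specific_gravity_avg``).  With
    ``scope="pooled"`` (or ``"per_visit"``) visit-level standardized logs
    are added to the visits table as ``exposure_log_std`` / ``mediator_log_std``.

    Passing an existing ``spec`` reuses its constants instead of
    recomputing them, which makes the operation idempotent.
    """
    if scope not in ("average", "pooled", "per_visit"):
        raise PreprocessingError(f"unknown standardization scope {scope!r}")
    if spec is not None and spec.scope != scope:
        raise PreprocessingError("spec scope does not match requested scope")
    subjects = table.subjects.copy()
    visits = table.visits.copy()
    wide = {col: table.wide(col) for col in BIOMARKERS}
    for col, mat in wide.items():
        if np.isnan(mat).any():
            raise PreprocessingError(f"missing {col} visits; impute before standardizing")
    out_spec = spec or StandardizationSpec(scope=scope)

    if scope == "average":
        for col, mat in wide.items():
            avg = np.log(mat).mean(axis=1)
            if spec is None:
                z, mean, sd = _standardize(avg, col)
                out_spec.means[col], out_spec.sds[col] = mean, sd
            else:
                z = spec.transform(col, avg)
            subjects[f"{col}_avg_std"] = z
        subjects["specific_gravity_avg"] = table.wide("specific_gravity").mean(axis=1)
    else:
        for col, mat in wide.items():
            logs = np.log(mat)
            if scope == "pooled":
                if spec is None:
                    _, mean, sd = _standardize(logs.ravel(), col)
                    out_spec.means[col], out_spec.sds[col] = mean, sd
                z = out_spec.transform(col, logs)
            else:  # per_visit
                z = np.empty_like(logs)
                for j, t in enumerate(VISITS):
                    key = f"{col}@t{t}"
                    if spec is None:
                        z[:, j], mean, sd = _standardize(logs[:, j], key)
                        out_spec.means[key], out_spec.sds[key] = mean, sd
                    else:
                        z[:, j] = spec.transform(key, logs[:, j])
            flat = pd.DataFrame(
                {
                    "subject_id": np.repeat(subjects["subject_id"].to_numpy(), N_VISITS),
                    "visit": np.tile(np.array(VISITS), len(subjects)),
                    f"{col}_log_std": z.ravel(),
                }
            )
            visits = visits.drop(columns=[f"{col}_log_std"], errors="ignore").merge(
                flat, on=["subject_id", "visit"], how="left"
            )
    return CohortTable(subjects=subjects, visits=visits), out_spec
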