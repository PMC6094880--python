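"""Longitudinal visit records: data model, validation and delimited-text I/O.

A cohort is one row per clinic visit with patient id, time since diagnosis in
years, the four outcomes, and a roster of binary clinical covariates.  Each
covariate carries a role:

* ``sign_symptom`` — signs/symptoms recorded at the visit (e.g. myalgia,
  dysphonia, periorbital rash, nail fold changes); candidates for Bayesian
  variable selection and imputed when missing.
* ``history_baseline`` — baseline history items; never imputed, because that
  would amount to imputing a participant's recollection.  Visits with any
  unobserved history item are excluded from analysis.
* ``treatment`` — treatment indicators (oral steroids, IV steroids,
  cyclophosphamide, ...); always kept in the model.

Missingness is explicit: a configurable token (default ``"NA"``) in files and
``NaN`` flags in memory — never a sentinel numeric value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .outcomes import OUTCOME_NAMES, OutcomeSpec, default_outcome_specs

__all__ = [
    "Covariate",
    "VisitRecord",
    "Cohort",
    "ExclusionReport",
    "CohortValidationError",
    "read_cohort",
    "filter_history_complete",
]

ROLES = ("sign_symptom", "history_baseline", "treatment")

BASE_COLUMNS = ("patient_id", "time_years", "ck", "cmas", "mmt8", "pga")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema or outcome bounds.

    Carries row-level diagnostics in :attr:`problems` (list of dicts with
    ``row``, ``column`` and ``message`` keys).
    """

    def __init__(self, message: str, problems: list[dict] | None = None):
        super().__init__(message)
        self.problems = problems or []


@dataclass(frozen=True)
class Covariate:
    """A named binary covariate with its modelling role."""

    name: str
    role: Literal["sign_symptom", "history_baseline", "treatment"]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown covariate role {self.role!r}")


@dataclass(frozen=True)
class VisitRecord:
    """One clinical visit (scalar view used by single-visit APIs)."""

    patient_id: str
    patient_index: int
    time_years: float
    outcomes: Mapping[str, float]          # observed outcomes only
    covariates: Mapping[str, float]        # 0/1, NaN if missing


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    ``df`` has columns ``patient_id`` (string), ``patient_index`` (dense int
    codes, contiguous after validation), ``time_years``, the four outcomes and
    one float column per covariate (0.0/1.0/NaN).  Visits of one patient are
    sorted by time.
    """

    df: pd.DataFrame
    covariates: list[Covariate]
    outcome_specs: dict[str, OutcomeSpec] = field(default_factory=default_outcome_specs)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_visits(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return int(self.df["patient_index"].nunique())

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def names_with_role(self, role: str) -> list[str]:
        return [c.name for c in self.covariates if c.role == role]

    @property
    def patient_ids(self) -> list[str]:
        """Original patient ids in dense-index order."""
        return list(
            self.df.drop_duplicates("patient_index")
            .sort_values("patient_index")["patient_id"]
        )

    def iter_visits(self) -> Iterator[VisitRecord]:
        cov_names = self.covariate_names
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            outcomes = {
                k: float(d[k]) for k in OUTCOME_NAMES if np.isfinite(d[k])
            }
            yield VisitRecord(
                patient_id=str(d["patient_id"]),
                patient_index=int(d["patient_index"]),
                time_years=float(d["time_years"]),
                outcomes=outcomes,
                covariates={k: float(d[k]) for k in cov_names},
            )

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        problems = _collect_problems(self.df, self.covariates, self.outcome_specs)
        if problems:
            raise CohortValidationError(
                f"{len(problems)} invalid values", problems
            )
        idx = np.sort(self.df["patient_index"].unique())
        if not np.array_equal(idx, np.arange(len(idx))):
            raise CohortValidationError("patient_index is not a dense 0..N-1 range")

    # -- I/O ------------------------------------------------------------------

    def write_csv(self, path: str | Path, missing_token: str = "NA") -> None:
        out = self.df.drop(columns=["patient_index"])
        out.to_csv(path, index=False, na_rep=missing_token)

    def fully_observed_patients(self) -> list[int]:
        """Dense indices of patients with no missing covariates or outcomes."""
        cols = list(OUTCOME_NAMES) + self.covariate_names
        complete = self.df[cols].notna().all(axis=1)
        by_patient = complete.groupby(self.df["patient_index"]).all()
        return [int(i) for i in by_patient.index[by_patient.values]]


@dataclass
class ExclusionReport:
    """Visits/patients dropped by :func:`filter_history_complete`."""

    dropped_visits: pd.DataFrame        # patient_id, time_years, reason
    dropped_patients: list[str]         # patients losing every visit
    patient_id_map: dict[str, int]      # retained id -> new dense index

    def to_csv(self, path: str | Path) -> None:
        self.dropped_visits.to_csv(path, index=False)


def _collect_problems(df, covariates, specs) -> list[dict]:
    problems: list[dict] = []
    if (df["time_years"] < 0).any() or (~np.isfinite(df["time_years"])).any():
        for r in df.index[(df["time_years"] < 0) | ~np.isfinite(df["time_years"])]:
            problems.append({"row": int(r), "column": "time_years",
                             "message": "time_since_diagnosis must be finite and >= 0"})
    for name in OUTCOME_NAMES:
        spec = specs[name]
        vals = df[name]
        if name == "ck":
            bad = vals.notna() & (vals <= 0)
            msg = "CK must be > 0 (log transform domain)"
        else:
            bad = vals.notna() & ((vals < spec.lower_bound) | (vals > spec.upper_bound))
            msg = f"{name} outside [{spec.lower_bound}, {spec.upper_bound}]"
        for r in df.index[bad]:
            problems.append({"row": int(r), "column": name, "message": msg})
    for cov in covariates:
        vals = df[cov.name]
        bad = vals.notna() & ~vals.isin([0.0, 1.0])
        for r in df.index[bad]:
            problems.append({"row": int(r), "column": cov.name,
                             "message": "binary covariate must be 0, 1 or missing"})
    return problems


def _densify(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (patient, time) and assign dense integer patient indices."""
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    order = {pid: i for i, pid in enumerate(pd.unique(df["patient_id"]))}
    df["patient_index"] = df["patient_id"].map(order).astype(int)
    df = df.sort_values(["patient_index", "time_years"], kind="stable")
    return df.reset_index(drop=True)


def build_cohort(
    df: pd.DataFrame,
    covariates: Sequence[Covariate],
    outcome_specs: dict[str, OutcomeSpec] | None = None,
) -> Cohort:
    """Assemble and validate a Cohort from a raw visit table."""
    covariates = list(covariates)
    specs = outcome_specs or default_outcome_specs()
    missing_cols = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    roster_names = {c.name for c in covariates}
    extra = [c for c in df.columns
             if c not in BASE_COLUMNS and c not in roster_names and c != "patient_index"]
    if extra:
        raise CohortValidationError(
            f"columns not in the covariate roster: {extra}"
        )
    absent = [n for n in roster_names if n not in df.columns]
    if absent:
        raise CohortValidationError(f"roster covariates absent from data: {absent}")
    df = df.copy()
    for c in list(OUTCOME_NAMES) + ["time_years"] + [c.name for c in covariates]:
        df[c] = pd.to_numeric(df[c], errors="raise")
    df = _densify(df)
    cohort = Cohort(df=df, covariates=covariates, outcome_specs=specs)
    cohort.validate()
    return cohort


def read_cohort(
    path: str | Path | io.TextIOBase,
    covariates: Sequence[Covariate],
    missing_token: str = "NA",
    outcome_specs: dict[str, OutcomeSpec] | None = None,
) -> Cohort:
    """Read a comma-delimited visit file into a validated :class:`Cohort`.

    The file must have a header row with ``patient_id, time_years, ck, cmas,
    mmt8, pga`` followed by exactly the roster covariates.  ``missing_token``
    marks unobserved cells.  Rows violating outcome bounds raise
    :class:`CohortValidationError` with row-level diagnostics.
    """
    df = pd.read_csv(
        path, na_values=[missing_token], keep_default_na=False, dtype={"patient_id": str}
    )
    return build_cohort(df, covariates, outcome_specs)


def filter_history_complete(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Drop visits with any unobserved baseline-history covariate.

    History items are never imputed; visits missing any of them are excluded,
    and patients losing all their visits are reported as excluded patients.
    Patient indices are re-densified on the retained cohort and the id → index
    mapping retained in the report.
    """
    history = cohort.names_with_role("history_baseline")
    df = cohort.df
    if not history:
        keep = pd.Series(True, index=df.index)
    else:
        keep = df[history].notna().all(axis=1)
    dropped = df.loc[~keep, ["patient_id", "time_years"]].copy()
    dropped["reason"] = "missing history_baseline covariate"
    retained = df.loc[keep].drop(columns=["patient_index"])
    before = set(df["patient_id"])
    after = set(retained["patient_id"])
    dropped_patients = sorted(before - after)
    new_df = _densify(retained)
    new_cohort = Cohort(
        df=new_df, covariates=list(cohort.covariates), outcome_specs=dict(cohort.outcome_specs)
    )
    id_map = {
        pid: int(ix)
        for pid, ix in new_df.drop_duplicates("patient_id")[["patient_id", "patient_index"]].values
    } if len(new_df) else {}
    report = ExclusionReport(
        dropped_visits=dropped.reset_index(drop=True),
        dropped_patients=dropped_patients,
        patient_id_map=id_map,
    )
    return new_cohort, report
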