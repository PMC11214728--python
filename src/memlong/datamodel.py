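"""Longitudinal data model and long-format CSV I/O.

A study dataset is a collection of subject series.  Every record carries two
time values: ``t_outcome`` (the outcome-model time scale, e.g. time since
baseline) and ``t_mem`` (the measurement-error-model time scale, e.g. age).
The two may coincide; when only one time column is supplied on disk it is
copied into both and a log message records this.

Missing numeric cells may be encoded as empty strings or ``NA``.  Main-study
files need not carry a true-exposure column; validation files must, and every
available (``present``) validation record must have a true exposure value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError, SchemaError

logger = logging.getLogger("memlong")

ROLE_MAIN = "main"
ROLE_VALIDATION = "validation"


@dataclass
class ObservationRecord:
    """One subject-occasion: outcome, surrogate/true exposure, covariates.

    ``present`` is the availability indicator I(s) for the exposure at this
    occasion; absent occasions never contribute to history functionals.
    """

    subject_id: str
    t_outcome: float
    t_mem: float
    surrogate: float
    true_exposure: float | None
    outcome: float | None
    covariates: np.ndarray
    present: bool = True


def _as_float_array(x, m):
    if x is None:
        return np.full(m, np.nan)
    a = np.asarray(x, dtype=float)
    if a.shape != (m,):
        raise SchemaError(f"expected length-{m} array, got shape {a.shape}")
    return a


@dataclass
class SubjectSeries:
    """One subject's occasions, ordered by outcome time.

    Fields are column arrays of equal length ``m`` (the number of occasions,
    m_i in the main study or l_i in the validation study); ``covariates`` is
    an (m, q) matrix, possibly with q = 0.
    """

    subject_id: str
    t_outcome: np.ndarray
    t_mem: np.ndarray = None
    surrogate: np.ndarray = None
    true_exposure: np.ndarray = None
    outcome: np.ndarray = None
    covariates: np.ndarray = None
    present: np.ndarray = None

    def __post_init__(self):
        self.t_outcome = np.asarray(self.t_outcome, dtype=float)
        m = self.t_outcome.size
        if m < 1:
            raise SchemaError(f"subject {self.subject_id}: needs >= 1 occasion")
        if m > 1 and not np.all(np.diff(self.t_outcome) > 0):
            raise FormatError(
                f"subject {self.subject_id}: outcome times must be strictly increasing"
            )
        self.t_mem = (
            self.t_outcome.copy() if self.t_mem is None else _as_float_array(self.t_mem, m)
        )
        self.surrogate = _as_float_array(self.surrogate, m)
        self.true_exposure = _as_float_array(self.true_exposure, m)
        self.outcome = _as_float_array(self.outcome, m)
        if self.covariates is None:
            self.covariates = np.empty((m, 0))
        else:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != m:
                raise SchemaError(
                    f"subject {self.subject_id}: covariates must have {m} rows"
                )
        if self.present is None:
            self.present = np.ones(m, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != (m,):
                raise SchemaError(f"subject {self.subject_id}: bad present mask")
        both_missing = (
            self.present & np.isnan(self.surrogate) & np.isnan(self.true_exposure)
        )
        if np.any(both_missing):
            raise SchemaError(
                f"subject {self.subject_id}: a present occasion must carry a "
                "surrogate or a true exposure value"
            )

    @property
    def m(self) -> int:
        return self.t_outcome.size

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def records(self) -> list[ObservationRecord]:
        out = []
        for j in range(self.m):
            out.append(
                ObservationRecord(
                    subject_id=self.subject_id,
                    t_outcome=float(self.t_outcome[j]),
                    t_mem=float(self.t_mem[j]),
                    surrogate=float(self.surrogate[j]),
                    true_exposure=None
                    if math.isnan(self.true_exposure[j])
                    else float(self.true_exposure[j]),
                    outcome=None if math.isnan(self.outcome[j]) else float(self.outcome[j]),
                    covariates=self.covariates[j],
                    present=bool(self.present[j]),
                )
            )
        return out


@dataclass
class StudyDataset:
    """A main or validation study: subject series plus role/design labels."""

    subjects: list
    role: str
    design: str | None = None

    def __post_init__(self):
        if self.role not in (ROLE_MAIN, ROLE_VALIDATION):
            raise SchemaError(f"unknown role {self.role!r}")
        qs = {s.n_covariates for s in self.subjects}
        if len(qs) > 1:
            raise SchemaError(f"covariate dimension varies within dataset: {sorted(qs)}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject ids in dataset")
        if self.role == ROLE_VALIDATION:
            for s in self.subjects:
                if np.any(s.present & np.isnan(s.true_exposure)):
                    raise SchemaError(
                        f"validation subject {s.subject_id}: true exposure missing "
                        "on a present occasion"
                    )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_covariates(self) -> int:
        return self.subjects[0].n_covariates if self.subjects else 0

    def ids(self) -> set:
        return {s.subject_id for s in self.subjects}

    def subset(self, keep_ids) -> "StudyDataset":
        keep = set(keep_ids)
        return StudyDataset(
            [s for s in self.subjects if s.subject_id in keep], self.role, self.design
        )


def check_design(main: StudyDataset, validation: StudyDataset, design: str) -> None:
    """Enforce IVS (validation ids a subset of main) or EVS (disjoint ids)."""
    design = design.lower()
    mids, vids = main.ids(), validation.ids()
    if design == "ivs":
        if not vids <= mids:
            raise DesignError("IVS requires every validation subject in the main study")
    elif design == "evs":
        if mids & vids:
            raise DesignError("EVS requires disjoint main/validation subject ids")
    else:
        raise DesignError(f"unknown design {design!r}")


# --- long-format CSV I/O ---------------------------------------------------

#: standard field -> default column name
DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "t_outcome": "t_outcome",
    "t_mem": "t_mem",
    "surrogate": "surrogate",
    "true_exposure": "true_exposure",
    "outcome": "outcome",
    "present": "present",
}

_NA_VALUES = ["", "NA"]


def read_long_table(path, column_map=None, role=ROLE_MAIN, covariate_columns=None):
    """Read a long-format (one row per subject-occasion) CSV.

    Parameters
    ----------
    column_map : dict, optional
        Mapping from standard field names (keys of :data:`DEFAULT_COLUMNS`)
        to the file's column names.  Unmapped fields use the defaults.
    role : {"main", "validation"}
    covariate_columns : list of str, optional
        Columns to load as the covariate vector W, in order.  Defaults to
        every column named ``W*`` in the file, sorted.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(
        path, na_values=_NA_VALUES, keep_default_na=True, float_precision="round_trip"
    )

    for key in ("subject_id", "t_outcome", "surrogate"):
        if cmap[key] not in df.columns:
            raise SchemaError(f"required column {cmap[key]!r} not found in {path}")
    if role == ROLE_VALIDATION and cmap["true_exposure"] not in df.columns:
        raise SchemaError(
            f"validation file {path} lacks true-exposure column {cmap['true_exposure']!r}"
        )
    if cmap["t_mem"] not in df.columns:
        logger.info(
            "no %r column in %s: copying outcome time into the MEM time scale",
            cmap["t_mem"],
            path,
        )
        df[cmap["t_mem"]] = df[cmap["t_outcome"]]

    if covariate_columns is None:
        reserved = set(cmap.values())
        covariate_columns = sorted(
            c for c in df.columns if c not in reserved and str(c).startswith("W")
        )

    if df.duplicated([cmap["subject_id"], cmap["t_outcome"]]).any():
        raise FormatError(f"duplicate (subject, t_outcome) rows in {path}")

    subjects = []
    for sid, g in df.groupby(cmap["subject_id"], sort=True):
        g = g.sort_values(cmap["t_outcome"])
        m = len(g)
        present = (
            g[cmap["present"]].fillna(0).astype(float).astype(bool).to_numpy()
            if cmap["present"] in g.columns
            else np.ones(m, dtype=bool)
        )
        subjects.append(
            SubjectSeries(
                subject_id=str(sid),
                t_outcome=g[cmap["t_outcome"]].to_numpy(float),
                t_mem=g[cmap["t_mem"]].to_numpy(float),
                surrogate=g[cmap["surrogate"]].to_numpy(float),
                true_exposure=g[cmap["true_exposure"]].to_numpy(float)
                if cmap["true_exposure"] in g.columns
                else None,
                outcome=g[cmap["outcome"]].to_numpy(float)
                if cmap["outcome"] in g.columns
                else None,
                covariates=g[covariate_columns].to_numpy(float) if covariate_columns else None,
                present=present,
            )
        )
    return StudyDataset(subjects, role=role)


def write_long_table(ds: StudyDataset, path) -> None:
    """Write a dataset back to long-format CSV (inverse of read_long_table)."""
    rows = []
    for s in ds.subjects:
        for j in range(s.m):
            row = {
                "subject_id": s.subject_id,
                "t_outcome": s.t_outcome[j],
                "t_mem": s.t_mem[j],
                "surrogate": s.surrogate[j],
                "true_exposure": s.true_exposure[j],
                "outcome": s.outcome[j],
                "present": int(s.present[j]),
            }
            for k in range(s.n_covariates):
                row[f"W{k + 1}"] = s.covariates[j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_report(fit, path, z=1.96) -> None:
    """Write a machine-readable coefficient table (CSV).

    Accepts a :class:`~memlong.stacked.StackedFit` (MEM block + outcome
    block) or any fit exposing ``coef_table()``.  Columns: block, term,
    estimate, se, ci_lower, ci_upper.  Estimates survive a read round-trip
    bit-exactly (full float repr).
    """
    if not getattr(fit, "converged", True):
        raise ValueError("refusing to report a non-converged fit")
    table = fit.coef_table(z=z)
    table.to_csv(path, index=False)


def read_fit_report(path) -> pd.DataFrame:
    # round_trip parsing so reported estimates reload bit-exactly
    return pd.read_csv(path, float_precision="round_trip")
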