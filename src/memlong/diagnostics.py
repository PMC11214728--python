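"""Empirical checks of the method's identifying assumptions.

* ``localized_error_test`` — in a validation study with repeated
  measurements, tests whether the true exposure depends on *past*
  surrogates once current-time surrogate, time and covariates are
  conditioned on.  Because past and current surrogates are typically
  collinear and validation studies small, the default is a two-step
  procedure: fit the current-time calibration model, then regress its
  residuals on the cumulative averages of the lagged surrogates (and lagged
  covariates) and jointly test those coefficients.  A one-step variant adds
  the lagged averages directly to the calibration model.
* ``surrogacy_test`` — with internal validation data (outcomes observed for
  validation subjects), adds the surrogate-history functional Z alongside
  the true-history functional X in the outcome model and jointly tests the
  Z coefficients; under surrogacy the surrogate carries no residual
  information.
* ``mem_equality_test`` — transportability-style Wald comparison of two
  independently fitted calibration models.
* ``confounder_screen`` — refits the outcome model without each candidate
  covariate set and flags sets whose removal moves the exposure-by-time
  coefficient by more than a chosen fraction (10% by default).

All tests use cluster-robust (sandwich) variances, matching the estimation
framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gee
from .datamodel import ROLE_VALIDATION, StudyDataset
from .exceptions import (
    DesignError,
    DomainError,
    InsufficientDataError,
    SpecificationError,
)
from .history import HistorySpec, subject_history
from .mem import expand_mem_terms, mem_design
from .stacked import _parse_outcome_terms, fit_naive


@dataclass
class AssumptionTestResult:
    """Joint Wald test outcome."""

    statistic: float
    df: int
    p_value: float
    test_kind: str
    terms_tested: list

    def __post_init__(self):
        if self.df < 1:
            raise DomainError("test needs at least one tested coefficient")


def _wald(fit: gee.GEEFit, test_idx, kind, names) -> AssumptionTestResult:
    V = fit.robust_vcov()
    q = fit.beta[test_idx]
    Vq = V[np.ix_(test_idx, test_idx)]
    stat = float(q @ np.linalg.solve(Vq, q)) if np.any(q) else 0.0
    df = len(test_idx)
    return AssumptionTestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        test_kind=kind,
        terms_tested=list(names),
    )


def _lagged_average(values: np.ndarray, j: int, m: int) -> float:
    """Mean of values at occasions j-1 .. j-m (0-based j)."""
    return float(values[j - m : j].mean())


def localized_error_test(
    vs: StudyDataset, lag: int, variant: str = "two_step"
) -> AssumptionTestResult:
    """Test the localized-error assumption in a repeated-measurement VS.

    ``lag`` = m, the number of past occasions whose surrogates (averaged)
    are allowed to matter under the alternative.
    """
    if lag < 1:
        raise DomainError("lag must be >= 1")
    if vs.role != ROLE_VALIDATION:
        raise DesignError("localized-error test needs a validation dataset")
    q = vs.n_covariates
    base_terms = ["intercept", "C", "t"] + [f"W{k + 1}" for k in range(q)]

    rows_D, rows_c, cluster = [], [], []
    lag_C, lag_W = [], []
    for s in vs.subjects:
        use = np.flatnonzero(s.present & np.isfinite(s.true_exposure) & np.isfinite(s.surrogate))
        C, tm, W, c = s.surrogate[use], s.t_mem[use], s.covariates[use], s.true_exposure[use]
        for jj in range(len(use)):
            if jj < lag:
                continue
            rows_D.append(mem_design(C[jj], tm[jj], W[jj], base_terms)[0])
            rows_c.append(c[jj])
            cluster.append(s.subject_id)
            lag_C.append(_lagged_average(C, jj, lag))
            lag_W.append([_lagged_average(W[:, k], jj, lag) for k in range(q)])
    if not rows_c:
        raise InsufficientDataError(f"no validation rows with {lag} prior occasions")

    lag_cols = np.column_stack([np.asarray(lag_C)] + ([np.asarray(lag_W)] if q else []))
    lag_names = ["lagavg:C"] + [f"lagavg:W{k + 1}" for k in range(q)]

    # cluster rows by subject for robust variances
    def clusters(D, y):
        order = {}
        for i, sid in enumerate(cluster):
            order.setdefault(sid, []).append(i)
        idx = list(order.values())
        return [D[i] for i in idx], [y[i] for i in idx]

    D0 = np.asarray(rows_D)
    c0 = np.asarray(rows_c)
    if variant == "one_step":
        D = np.hstack([D0, lag_cols])
        Ds, ys = clusters(D, c0)
        fit = gee.gee_solve(Ds, ys, structure="independence", terms=base_terms + lag_names)
        test_idx = [len(base_terms) + k for k in range(lag_cols.shape[1])]
        return _wald(fit, test_idx, "localized_error:one_step", lag_names)
    if variant != "two_step":
        raise SpecificationError(f"unknown variant {variant!r}")

    # step 1: current-time calibration model on the same rows
    Ds, ys = clusters(D0, c0)
    step1 = gee.gee_solve(Ds, ys, structure="independence", terms=base_terms)
    resid = c0 - D0 @ step1.beta
    # step 2: residuals on lagged averages
    D2 = np.hstack([np.ones((len(resid), 1)), lag_cols])
    Ds2, ys2 = clusters(D2, resid)
    step2 = gee.gee_solve(Ds2, ys2, structure="independence", terms=["intercept"] + lag_names)
    test_idx = list(range(1, 1 + lag_cols.shape[1]))
    return _wald(step2, test_idx, "localized_error:two_step", lag_names)


def surrogacy_test(
    ivs: StudyDataset,
    history: HistorySpec = HistorySpec(),
    outcome_terms=("intercept", "X", "t", "X:t"),
) -> AssumptionTestResult:
    """Joint test that the surrogate history is uninformative given the true.

    Requires internal-validation data: outcomes and true exposures observed
    on the same subjects.  Fits the outcome model with the true-history
    functional X plus the surrogate-history functional Z (and Z x t when the
    model carries X x t) and tests the Z coefficients.
    """
    usable = [
        s
        for s in ivs.subjects
        if np.any(np.isfinite(s.outcome)) and np.any(np.isfinite(s.true_exposure))
    ]
    if not usable:
        raise DesignError(
            "surrogacy test needs internal-validation subjects with outcomes "
            "and true exposures (not available under an external design)"
        )
    terms = _parse_outcome_terms(outcome_terms, ivs.n_covariates)
    z_terms = ["Z"] + (["Z:t"] if "X:t" in terms else [])
    designs, outcomes = [], []
    for s in usable:
        xv, xd = subject_history(s, history, source="true")
        zv, zd = subject_history(s, history, source="surrogate")
        keep = xd & zd & np.isfinite(s.outcome)
        if not np.any(keep):
            continue
        X = gee.build_design(s, np.where(np.isfinite(xv), xv, 0.0), terms, keep=keep)
        zcols = [zv[keep]]
        if "Z:t" in z_terms:
            zcols.append(zv[keep] * s.t_outcome[keep])
        designs.append(np.column_stack([X] + zcols))
        outcomes.append(s.outcome[keep])
    fit = gee.gee_solve(
        designs, outcomes, structure="independence", terms=list(terms) + z_terms
    )
    test_idx = [len(terms) + k for k in range(len(z_terms))]
    return _wald(fit, test_idx, "surrogacy", z_terms)


def mem_equality_test(
    vs_a: StudyDataset, vs_b: StudyDataset, terms, working="independence"
) -> AssumptionTestResult:
    """Wald test of equality of two calibration-model coefficient vectors.

    The two validation samples are treated as independent; each fit
    contributes its own sandwich variance.
    """
    from .mem import fit_mem

    qa, qb = vs_a.n_covariates, vs_b.n_covariates
    if expand_mem_terms(terms, qa) != expand_mem_terms(terms, qb):
        raise SpecificationError("term lists resolve differently in the two samples")
    fa = fit_mem(vs_a, terms, working=working)
    fb = fit_mem(vs_b, terms, working=working)
    delta = fa.alpha - fb.alpha
    V = fa.robust_vcov() + fb.robust_vcov()
    stat = float(delta @ np.linalg.solve(V, delta)) if np.any(delta) else 0.0
    df = delta.size
    return AssumptionTestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        test_kind="mem_equality",
        terms_tested=list(fa.params.terms),
    )


def confounder_screen(
    ms: StudyDataset,
    candidate_sets: dict,
    threshold: float = 0.10,
    history: HistorySpec = HistorySpec(),
    outcome_terms=("intercept", "X", "t", "X:t", "W"),
    working="ar1",
) -> pd.DataFrame:
    """Change-in-estimate screen for candidate confounder sets.

    Refits the (uncorrected) outcome model dropping each candidate set of
    covariate terms and reports the relative change in the exposure-by-time
    coefficient; sets whose removal moves it by more than ``threshold`` are
    flagged as confounders to retain.
    """
    full_terms = _parse_outcome_terms(outcome_terms, ms.n_covariates)
    full = fit_naive(ms, history=history, outcome_terms=full_terms, working=working)
    b3_full = full.params.coef("X:t")
    rows = []
    for name, dropped in candidate_sets.items():
        dropped = gee.expand_w_terms(list(dropped), ms.n_covariates)
        missing = [d for d in dropped if d not in full_terms]
        if missing:
            raise SpecificationError(f"candidate set {name!r} not nested: {missing}")
        reduced_terms = [t for t in full_terms if t not in dropped]
        red = fit_naive(ms, history=history, outcome_terms=reduced_terms, working=working)
        b3_red = red.params.coef("X:t")
        change = abs(b3_red - b3_full) / abs(b3_full)
        rows.append(
            {
                "candidate_set": name,
                "dropped_terms": ",".join(dropped),
                "beta3_full": b3_full,
                "beta3_reduced": b3_red,
                "relative_change": change,
                "flagged": change > threshold,
            }
        )
    return pd.DataFrame(rows)
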