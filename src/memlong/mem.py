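"""Measurement error model (MEM): calibration of true on surrogate exposure.

Fitted in the validation study, where paired (true, surrogate) exposures are
observed.  The mean model is the linear predictor

    f(C, t, W; alpha) = a0 + a1 C + a2 t + a3 C t + a4' W

with any subset of terms from {intercept, C, t, C:t, W...}.  The time
variable is always the MEM time scale (``t_mem``, e.g. age) — an external
validation study may carry no outcome-model time at all, and the two scales
are allowed to differ throughout the package.

With a single validation measurement per subject the estimating equation
reduces exactly to ordinary least squares; with repeated measurements it is
a GEE with a chosen working correlation.  Per-subject score contributions
psi_alpha_i = D_i' V_i^{-1} (c_i - f_i) are retained for the stacked
sandwich variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gee
from .datamodel import ROLE_VALIDATION, StudyDataset
from .exceptions import SchemaError, ShapeError, SpecificationError

MEM_TERM_CHOICES = ("intercept", "C", "t", "C:t", "W")


@dataclass
class MEMParams:
    """alpha with its ordered term names (W expanded to W1..Wq)."""

    alpha: np.ndarray
    terms: list

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.size != len(self.terms):
            raise ShapeError("alpha length must match term list")

    @property
    def p_alpha(self) -> int:
        return self.alpha.size

    @property
    def n_covariates(self) -> int:
        return sum(1 for t in self.terms if t.startswith("W"))

    def coef(self, term) -> float:
        return float(self.alpha[list(self.terms).index(term)])


@dataclass
class MEMFit:
    """Fitted MEM with per-subject scores for the stacked sandwich."""

    params: MEMParams
    score_contributions: np.ndarray  # (n2, p_alpha)
    bread_block: np.ndarray  # d(sum psi_alpha)/d(alpha)
    working: str
    converged: bool
    subject_ids: list
    n_iter: int = 0

    @property
    def alpha(self) -> np.ndarray:
        return self.params.alpha

    def robust_vcov(self) -> np.ndarray:
        A = self.score_contributions.T @ self.score_contributions
        Binv = np.linalg.inv(self.bread_block)
        return Binv @ A @ Binv.T

    def coef_table(self, z=1.96):
        import pandas as pd

        se = np.sqrt(np.diag(self.robust_vcov()))
        est = self.params.alpha
        return pd.DataFrame(
            {
                "block": "mem",
                "term": list(self.params.terms),
                "estimate": est,
                "se": se,
                "ci_lower": est - z * se,
                "ci_upper": est + z * se,
            }
        )


def expand_mem_terms(terms, q):
    out = []
    for t in terms:
        if t == "W":
            out.extend(f"W{k + 1}" for k in range(q))
        elif t in MEM_TERM_CHOICES or (t.startswith("W") and t[1:].isdigit()):
            out.append(t)
        else:
            raise SpecificationError(f"unknown MEM term {t!r}")
    return out


def mem_design(C, t_mem, W, terms) -> np.ndarray:
    """Design matrix of the MEM linear predictor, one row per record."""
    C = np.atleast_1d(np.asarray(C, dtype=float))
    t_mem = np.atleast_1d(np.asarray(t_mem, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float)) if W is not None else np.empty((C.size, 0))
    if W.shape[0] != C.size:
        W = W.reshape(C.size, -1)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(C.size))
        elif term == "C":
            cols.append(C)
        elif term == "t":
            cols.append(t_mem)
        elif term == "C:t":
            cols.append(C * t_mem)
        elif term.startswith("W"):
            k = int(term[1:]) - 1
            if k >= W.shape[1]:
                raise ShapeError(f"MEM term {term} beyond covariate width {W.shape[1]}")
            cols.append(W[:, k])
        else:
            raise SpecificationError(f"unknown MEM term {term!r}")
    return np.column_stack(cols)


def mem_predict(params: MEMParams, C, t_mem, W=None):
    """Calibrated value f(C, t_mem, W; alpha); vectorised over records."""
    scalar = np.isscalar(C) or np.asarray(C).ndim == 0
    D = mem_design(C, t_mem, W, params.terms)
    out = D @ params.alpha
    return float(out[0]) if scalar else out


def fit_mem(vs: StudyDataset, terms, working="independence") -> MEMFit:
    """Fit the MEM in the validation study.

    Uses the generic estimating-equation solver with subjects as clusters;
    a single measurement per subject makes any working choice collapse to
    ordinary least squares.
    """
    if vs.role != ROLE_VALIDATION:
        raise SchemaError("MEM must be fitted on a validation-role dataset")
    terms = expand_mem_terms(terms, vs.n_covariates)
    designs, outcomes, ids = [], [], []
    for s in vs.subjects:
        use = s.present & np.isfinite(s.true_exposure) & np.isfinite(s.surrogate)
        if not np.any(use):
            continue
        designs.append(mem_design(s.surrogate[use], s.t_mem[use], s.covariates[use], terms))
        outcomes.append(s.true_exposure[use])
        ids.append(s.subject_id)
    if not designs:
        raise SchemaError("no usable validation records")
    fit = gee.gee_solve(designs, outcomes, structure=working, terms=terms)
    return MEMFit(
        params=MEMParams(fit.beta, terms),
        score_contributions=fit.score_contributions,
        bread_block=fit.bread_block,
        working=working,
        converged=fit.converged,
        subject_ids=ids,
        n_iter=fit.n_iter,
    )
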