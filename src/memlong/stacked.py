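"""Two-stage corrected estimator and the stacked sandwich variance.

Stage 1 fits the measurement error model in the validation study (alpha);
stage 2 replaces the unobservable true-exposure history functional X by its
calibrated expectation X_hat under alpha_hat and solves the outcome
estimating equations for beta.  Because the stacked system

    psi(theta) = [psi_alpha(alpha); psi_beta(alpha, beta)] = 0

is block triangular, the two-stage solution solves it exactly.

Inference uses the M-estimation sandwich

    Var(theta_hat) = B^{-1} A (B^{-1})',   theta = (alpha', beta')',

with A = sum_i psi_i psi_i' over per-subject stacked scores and B the block
lower-triangular Jacobian [[dpsi_a/da, 0], [dpsi_b/da, dpsi_b/db]].  The
cross block propagates the validation-stage uncertainty in alpha into the
outcome-stage inference.  Subjects appearing only in the validation study
contribute (psi_alpha_i, 0); main-study-only subjects contribute
(0, psi_beta_i); internal-validation subjects contribute both pieces
concatenated, which is what makes the A cross block nonzero under IVS.

The uncorrected ("naive") estimator, which plugs the surrogate history
functional Z straight into the outcome model, is provided for comparison;
under a no-interaction MEM its exposure coefficients attenuate by the
calibration slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gee
from .datamodel import ROLE_MAIN, StudyDataset, check_design
from .exceptions import DesignError, InferenceError, SchemaError
from .history import HistorySpec, calibration_matrix, subject_history
from .mem import MEMFit, expand_mem_terms, fit_mem, mem_design

logger = logging.getLogger("memlong")

DEFAULT_OUTCOME_TERMS = ("intercept", "X", "t", "X:t")
DEFAULT_MEM_TERMS = ("intercept", "C")


@dataclass
class StackedFit:
    """theta_hat = (alpha_hat, beta_hat) with its stacked sandwich blocks."""

    alpha: np.ndarray
    beta: np.ndarray
    mem_terms: list
    outcome_terms: list
    A: np.ndarray
    B: np.ndarray
    vcov: np.ndarray | None
    design: str
    mem_fit: MEMFit = field(repr=False, default=None)
    outcome_fit: gee.GEEFit = field(repr=False, default=None)
    naive_companion: gee.GEEFit | None = field(repr=False, default=None)
    converged: bool = True

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    @property
    def p_alpha(self) -> int:
        return self.alpha.size

    @property
    def term_names(self) -> list:
        return [f"alpha:{t}" for t in self.mem_terms] + [
            f"beta:{t}" for t in self.outcome_terms
        ]

    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise InferenceError("sandwich variance unavailable (singular bread)")
        return np.sqrt(np.diag(self.vcov))

    def beta_vcov(self) -> np.ndarray:
        if self.vcov is None:
            raise InferenceError("sandwich variance unavailable (singular bread)")
        return self.vcov[self.p_alpha :, self.p_alpha :]

    def coef(self, term: str) -> float:
        """Coefficient by stacked name, e.g. ``beta:X:t`` or ``alpha:C``."""
        return float(self.theta[self.term_names.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se()[self.term_names.index(term)])

    def coef_table(self, z=1.96) -> pd.DataFrame:
        se = self.se()
        est = self.theta
        block = ["mem"] * len(self.mem_terms) + ["outcome"] * len(self.outcome_terms)
        return pd.DataFrame(
            {
                "block": block,
                "term": list(self.mem_terms) + list(self.outcome_terms),
                "estimate": est,
                "se": se,
                "ci_lower": est - z * se,
                "ci_upper": est + z * se,
            }
        )


def _outcome_rows(series, xvals, defined, terms):
    """Design/response for one subject's usable outcome rows."""
    keep = defined & np.isfinite(series.outcome)
    if not np.any(keep):
        return None
    X = gee.build_design(series, np.where(np.isfinite(xvals), xvals, 0.0), terms, keep=keep)
    return X, series.outcome[keep], np.flatnonzero(keep)


def _occasion_positions(series, keep_idx, grid):
    pos = np.searchsorted(grid, series.t_outcome[keep_idx])
    pos = np.clip(pos, 0, len(grid) - 1)
    return list(pos)


def _collect_outcome_clusters(ms, xhats, terms, grid=None):
    designs, outcomes, ids, occ_idx, used = [], [], [], [], []
    for i, (s, (xv, defined)) in enumerate(zip(ms.subjects, xhats)):
        rows = _outcome_rows(s, xv, defined, terms)
        if rows is None:
            continue
        X, y, keep_idx = rows
        designs.append(X)
        outcomes.append(y)
        ids.append(s.subject_id)
        used.append(i)
        if grid is not None:
            occ_idx.append(_occasion_positions(s, keep_idx, grid))
    return designs, outcomes, ids, (occ_idx if grid is not None else None), used


def _infer_occasion_grid(ms):
    return np.unique(np.concatenate([s.t_outcome for s in ms.subjects]))


def _parse_outcome_terms(terms, q):
    terms = gee.expand_w_terms(terms, q)
    if ("X:t" in terms) != ("X" in terms):
        from .exceptions import SpecificationError

        raise SpecificationError("outcome terms must carry X and X:t together")
    return terms


def fit_naive(
    ms: StudyDataset,
    history: HistorySpec = HistorySpec(),
    outcome_terms=DEFAULT_OUTCOME_TERMS,
    working="ar1",
) -> gee.GEEFit:
    """Uncorrected fit: the surrogate history functional Z stands in for X."""
    terms = _parse_outcome_terms(outcome_terms, ms.n_covariates)
    zhats = [subject_history(s, history, source="surrogate") for s in ms.subjects]
    grid = _infer_occasion_grid(ms) if working == "unstructured" else None
    designs, outcomes, _, occ, _ = _collect_outcome_clusters(ms, zhats, terms, grid)
    return gee.gee_solve(
        designs,
        outcomes,
        structure=working,
        terms=terms,
        occasion_index=occ,
        occasion_grid=grid,
    )


def _mem_design_fn(mem_terms):
    return lambda C, t_mem, W: mem_design(C, t_mem, W, mem_terms)


def cross_jacobian(alpha, psi_beta_fn, rel_step=1e-6) -> np.ndarray:
    """Central-difference d(sum psi_beta)/d(alpha) at the stacked solution.

    Step h_k = rel_step * (1 + |alpha_k|) per coordinate.  The outcome
    working covariance is held fixed inside ``psi_beta_fn``.
    """
    alpha = np.asarray(alpha, dtype=float)
    cols = []
    for k in range(alpha.size):
        h = rel_step * (1.0 + abs(alpha[k]))
        ap = alpha.copy()
        am = alpha.copy()
        ap[k] += h
        am[k] -= h
        cols.append((psi_beta_fn(ap) - psi_beta_fn(am)) / (2.0 * h))
    return np.column_stack(cols)


def assemble_sandwich(
    psi_alpha, alpha_ids, psi_beta, beta_ids, design, B_aa, B_bb, B_ba
):
    """Stack per-subject scores and form Var(theta) = B^{-1} A B^{-T}.

    EVS: validation subjects contribute (psi_alpha_i, 0) and main-study
    subjects (0, psi_beta_i), so the A cross block vanishes.  IVS: subjects
    in both studies contribute the concatenated score, coupling the blocks.
    """
    psi_alpha = np.asarray(psi_alpha, dtype=float)
    psi_beta = np.asarray(psi_beta, dtype=float)
    pa = psi_alpha.shape[1] if psi_alpha.ndim == 2 else 0
    pb = psi_beta.shape[1]
    a_index = {sid: i for i, sid in enumerate(alpha_ids)}
    b_index = {sid: i for i, sid in enumerate(beta_ids)}
    subjects = list(dict.fromkeys(list(alpha_ids) + list(beta_ids)))
    A = np.zeros((pa + pb, pa + pb))
    for sid in subjects:
        psi = np.zeros(pa + pb)
        if sid in a_index:
            psi[:pa] = psi_alpha[a_index[sid]]
        if sid in b_index:
            psi[pa:] = psi_beta[b_index[sid]]
        A += np.outer(psi, psi)
    if design == "evs":
        # disjoint studies: zero the cross block exactly (no shared subjects)
        A[:pa, pa:] = 0.0
        A[pa:, :pa] = 0.0
    B = np.zeros((pa + pb, pa + pb))
    B[:pa, :pa] = B_aa
    B[pa:, :pa] = B_ba
    B[pa:, pa:] = B_bb
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise InferenceError("singular bread matrix B") from exc
    if not np.all(np.isfinite(Binv)):
        raise InferenceError("singular bread matrix B")
    vcov = Binv @ A @ Binv.T
    vcov = (vcov + vcov.T) / 2.0
    return A, B, vcov


def fit_corrected(
    ms: StudyDataset,
    vs: StudyDataset,
    history: HistorySpec = HistorySpec(),
    mem_terms=DEFAULT_MEM_TERMS,
    outcome_terms=DEFAULT_OUTCOME_TERMS,
    working="ar1",
    mem_working="independence",
    design=None,
    include_validation_outcomes=True,
    compute_vcov=True,
    compute_naive=False,
) -> StackedFit:
    """Measurement-error-corrected fit of the longitudinal outcome model.

    Parameters
    ----------
    ms, vs : main-study and validation-study datasets
    history : which exposure-history functional the outcome model uses
    mem_terms : MEM term list, e.g. ("intercept", "C", "t", "C:t", "W")
    outcome_terms : outcome-model term list (X denotes the history functional)
    working : outcome-model working correlation
    mem_working : validation-stage working correlation (irrelevant when
        each validation subject has one measurement)
    design : "ivs" | "evs"; inferred from the id sets when omitted
    include_validation_outcomes : under IVS, keep validation subjects'
        outcome rows in the outcome-stage estimating equation (they then
        contribute both score pieces); set False for sensitivity analyses
    compute_vcov : skip the sandwich (point estimates only) when False

    Notes
    -----
    Internal-validation subjects use the calibrated history X_hat in the
    outcome stage just like everyone else, not their observed true
    exposures.
    """
    if ms.role != ROLE_MAIN:
        raise SchemaError("first dataset must have role='main'")
    if design is None:
        vids, mids = vs.ids(), ms.ids()
        if vids & mids:
            design = "ivs"
        else:
            design = "evs"
    design = design.lower()
    check_design(ms, vs, design)

    mem_fit = fit_mem(vs, mem_terms, working=mem_working)
    mem_terms_x = mem_fit.params.terms
    terms = _parse_outcome_terms(outcome_terms, ms.n_covariates)

    outcome_ds = ms
    if design == "ivs" and not include_validation_outcomes:
        outcome_ds = ms.subset(ms.ids() - vs.ids())

    # per-subject calibration matrices: X_hat_i = G_i @ alpha
    dfn = _mem_design_fn(mem_terms_x)
    gmats = [calibration_matrix(s, history, dfn) for s in outcome_ds.subjects]
    alpha = mem_fit.alpha
    xhats = [(G @ alpha, defined) for G, defined in gmats]

    grid = _infer_occasion_grid(outcome_ds) if working == "unstructured" else None
    designs, outcomes, beta_ids, occ, used = _collect_outcome_clusters(
        outcome_ds, xhats, terms, grid
    )
    out_fit = gee.gee_solve(
        designs,
        outcomes,
        structure=working,
        terms=terms,
        occasion_index=occ,
        occasion_grid=grid,
    )
    beta = out_fit.beta

    naive = (
        fit_naive(ms, history=history, outcome_terms=outcome_terms, working=working)
        if compute_naive
        else None
    )

    A = B = vcov = None
    if compute_vcov:
        fit_units = [(gmats[i], outcome_ds.subjects[i]) for i in used]
        x_col = terms.index("X") if "X" in terms else None
        xt_col = terms.index("X:t") if "X:t" in terms else None

        def psi_beta_sum(a):
            per = []
            for ((G, defined), s), X0 in zip(fit_units, designs):
                xv = G @ a
                keep = defined & np.isfinite(s.outcome)
                X = X0.copy()
                kept_x = xv[keep]
                if x_col is not None:
                    X[:, x_col] = kept_x
                if xt_col is not None:
                    X[:, xt_col] = kept_x * s.t_outcome[keep]
                per.append(X)
            return gee.psi_sum(per, outcomes, beta, out_fit.working, out_fit.occasion_index)

        B_ba = cross_jacobian(alpha, psi_beta_sum)
        try:
            A, B, vcov = assemble_sandwich(
                mem_fit.score_contributions,
                mem_fit.subject_ids,
                out_fit.score_contributions,
                beta_ids,
                design,
                mem_fit.bread_block,
                out_fit.bread_block,
                B_ba,
            )
        except InferenceError:
            logger.warning("singular bread matrix: returning point estimates only")
            vcov = None

    return StackedFit(
        alpha=alpha,
        beta=beta,
        mem_terms=mem_terms_x,
        outcome_terms=terms,
        A=A,
        B=B,
        vcov=vcov,
        design=design,
        mem_fit=mem_fit,
        outcome_fit=out_fit,
        naive_companion=naive,
        converged=mem_fit.converged and out_fit.converged,
    )
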