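"""Generic estimating-equation machinery for marginal linear models.

Solves sum_i X_i' V_i^{-1} (y_i - X_i beta) = 0 by iterating a weighted
least-squares update with a moment update of the working covariance
V_i = phi R_i, where R_i follows one of the structures below.  Because the
mean model is linear, each update is a single linear solve; iteration is
only needed because R depends on the residuals.

Working structures
------------------
independence   R = I
exchangeable   R[j,k] = rho for j != k
ar1            R[j,k] = rho^{|j-k|} (occasion-position distance)
unstructured   entries estimated by available-pairs moments on a declared
               common occasion grid

Moment estimators (residuals e at the current iterate):
  phi  = sum e^2 / (N_obs - p)
  ar1  rho = [sum_i sum_j e_ij e_i,j+1] / [phi sum_i (m_i - 1)], clamped
         to (-0.99, 0.99)
  exch rho = [sum_i sum_{j<k} e_ij e_ik] / [phi sum_i m_i (m_i - 1) / 2]
  unstructured R[a,b] = [sum over subjects with both occasions of e_a e_b]
         / (n_ab phi), diagonal fixed at 1

The per-subject scores psi_i = X_i' V_i^{-1} (y_i - X_i beta_hat) and the
bread d(sum psi)/d(beta) = -sum X_i' V_i^{-1} X_i feed the stacked sandwich.
The working covariance is treated as fixed at its moment estimate in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConvergenceError,
    DomainError,
    ShapeError,
    SingularDesignError,
    SpecificationError,
)

STRUCTURES = ("independence", "ar1", "exchangeable", "unstructured")

MAX_ITER = 50
TOL = 1e-8


@dataclass
class OutcomeParams:
    """Coefficient vector with its ordered term names."""

    beta: np.ndarray
    terms: list

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.size != len(self.terms):
            raise ShapeError("beta length must match term list")
        # the exposure-by-time interaction only makes sense alongside the
        # main effect, and the divergence model always carries both
        if ("X:t" in self.terms) != ("X" in self.terms):
            raise SpecificationError("X and X:t terms must appear together")

    @property
    def p_beta(self) -> int:
        return self.beta.size

    def coef(self, term) -> float:
        return float(self.beta[list(self.terms).index(term)])


@dataclass
class WorkingCov:
    """Working covariance: structure label, correlation parameter(s), scale."""

    structure: str
    rho: float | np.ndarray | None
    phi: float
    occasion_grid: np.ndarray | None = None

    def correlation(self, m: int = None, occ_idx=None) -> np.ndarray:
        """Correlation matrix for a cluster of size m (or grid positions)."""
        if self.structure == "unstructured":
            R = self.rho if occ_idx is None else self.rho[np.ix_(occ_idx, occ_idx)]
            return np.asarray(R)
        if m is None:
            m = len(occ_idx)
        if self.structure == "independence" or m == 1:
            return np.eye(m)
        if self.structure == "ar1":
            idx = np.arange(m)
            return self.rho ** np.abs(idx[:, None] - idx[None, :])
        if self.structure == "exchangeable":
            return np.full((m, m), self.rho) + (1.0 - self.rho) * np.eye(m)
        raise DomainError(f"unknown working structure {self.structure!r}")


@dataclass
class GEEFit:
    """Solution of the estimating equations with per-subject scores."""

    params: OutcomeParams
    working: WorkingCov
    score_contributions: np.ndarray  # (n_clusters, p)
    bread_block: np.ndarray  # d(sum psi)/d(beta), p x p (negative definite)
    n_iter: int
    converged: bool
    residuals: list = field(repr=False, default=None)
    occasion_index: list = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return self.params.beta

    def robust_vcov(self) -> np.ndarray:
        """Cluster-robust sandwich B^{-1} A B^{-T} with A = sum psi psi'."""
        A = self.score_contributions.T @ self.score_contributions
        Binv = np.linalg.inv(self.bread_block)
        return Binv @ A @ Binv.T

    def coef_table(self, z=1.96):
        import pandas as pd

        se = np.sqrt(np.diag(self.robust_vcov()))
        est = self.params.beta
        return pd.DataFrame(
            {
                "block": "outcome",
                "term": list(self.params.terms),
                "estimate": est,
                "se": se,
                "ci_lower": est - z * se,
                "ci_upper": est + z * se,
            }
        )


def build_design(series, xvals, terms, keep=None):
    """Design rows (1, X, t, X t, W') for one subject's retained occasions.

    ``xvals`` holds the history value per occasion; ``keep`` masks occasions
    retained for fitting (defaults to all).  Row order follows occasion
    order.
    """
    xvals = np.asarray(xvals, dtype=float)
    if xvals.shape != (series.m,):
        raise ShapeError("one history value required per occasion")
    if keep is None:
        keep = np.ones(series.m, dtype=bool)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(series.m))
        elif term == "X":
            cols.append(xvals)
        elif term == "t":
            cols.append(series.t_outcome)
        elif term == "X:t":
            cols.append(xvals * series.t_outcome)
        elif term.startswith("W"):
            k = int(term[1:]) - 1
            if k >= series.n_covariates:
                raise ShapeError(f"covariate term {term} beyond dataset width")
            cols.append(series.covariates[:, k])
        else:
            raise SpecificationError(f"unknown outcome term {term!r}")
    return np.column_stack(cols)[keep]


def expand_w_terms(terms, q):
    """Expand a bare "W" into W1..Wq; pass other terms through."""
    out = []
    for t in terms:
        if t == "W":
            out.extend(f"W{k + 1}" for k in range(q))
        else:
            out.append(t)
    return out


def estimate_working(residuals, structure, p, occasion_index=None, occasion_grid=None):
    """Moment estimates of (phi, rho) from per-cluster residual vectors."""
    if structure not in STRUCTURES:
        raise DomainError(f"unknown working structure {structure!r}")
    n_obs = sum(e.size for e in residuals)
    sse = sum(float(e @ e) for e in residuals)
    dof = max(n_obs - p, 1)
    # floor guards the degenerate perfect-fit case (zero residuals)
    phi = max(sse / dof, 1e-12)
    rho = None
    if structure == "ar1":
        num = sum(float(e[:-1] @ e[1:]) for e in residuals if e.size > 1)
        den = phi * sum(e.size - 1 for e in residuals)
        rho = 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))
    elif structure == "exchangeable":
        num = 0.0
        npairs = 0
        for e in residuals:
            s = e.sum()
            num += (s * s - e @ e) / 2.0
            npairs += e.size * (e.size - 1) // 2
        rho = 0.0 if npairs == 0 else float(np.clip(num / (phi * npairs), -0.99, 0.99))
    elif structure == "unstructured":
        if occasion_grid is None or occasion_index is None:
            raise SpecificationError(
                "unstructured working correlation needs a common occasion grid"
            )
        G = len(occasion_grid)
        M = np.zeros((G, G))
        cnt = np.zeros((G, G))
        for e, idx in zip(residuals, occasion_index):
            idx = np.asarray(idx)
            M[np.ix_(idx, idx)] += np.outer(e, e)
            cnt[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.where(cnt > 0, M / np.maximum(cnt, 1) / phi, 0.0)
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2.0
        # shrink toward identity if the moment estimate is not PD
        w = np.linalg.eigvalsh(R)
        if w.min() < 1e-8:
            lam = min(1.0, (1e-6 - w.min()) / (1.0 - w.min()))
            R = (1 - lam) * R + lam * np.eye(G)
        rho = R
    return WorkingCov(structure, rho, phi, occasion_grid=np.asarray(occasion_grid) if occasion_grid is not None else None)


def _group_clusters(designs, outcomes, occasion_index, structure):
    """Group clusters sharing a correlation pattern so solves batch."""
    groups = {}
    for i, (X, y) in enumerate(zip(designs, outcomes)):
        if structure == "unstructured":
            key = tuple(occasion_index[i])
        else:
            key = X.shape[0]
        groups.setdefault(key, []).append(i)
    return groups


def _accumulate(groups, designs, outcomes, beta, working, structure):
    """One pass: returns (XtVX, XtVy, psi (n,p), residuals list)."""
    p = designs[0].shape[1]
    n = len(designs)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    psi = np.zeros((n, p))
    residuals = [None] * n
    for key, idx in groups.items():
        m = designs[idx[0]].shape[0]
        if structure == "unstructured":
            Rinv = np.linalg.inv(working.correlation(occ_idx=list(key)))
        else:
            Rinv = np.linalg.inv(working.correlation(m=m))
        Xg = np.stack([designs[i] for i in idx])  # (g, m, p)
        yg = np.stack([outcomes[i] for i in idx])  # (g, m)
        XtR = np.einsum("gmp,mn->gnp", Xg, Rinv)
        XtVX += np.einsum("gnp,gnq->pq", XtR, Xg)
        XtVy += np.einsum("gnp,gn->p", XtR, yg)
        if beta is not None:
            rg = yg - Xg @ beta
            psi_g = np.einsum("gnp,gn->gp", XtR, rg) / working.phi
            for jj, i in enumerate(idx):
                psi[i] = psi_g[jj]
                residuals[i] = rg[jj]
    return XtVX, XtVy, psi, residuals


def gee_solve(
    designs,
    outcomes,
    structure="independence",
    terms=None,
    occasion_index=None,
    occasion_grid=None,
    fixed_working=None,
    max_iter=MAX_ITER,
    tol=TOL,
) -> GEEFit:
    """Solve the estimating equations for a linear marginal model.

    Parameters
    ----------
    designs, outcomes : lists of per-cluster arrays, X_i (m_i, p), y_i (m_i,)
    structure : working correlation label
    occasion_index : per-cluster positions on ``occasion_grid`` (required
        for ``unstructured`` with ragged clusters)
    fixed_working : WorkingCov, optional
        Skip moment estimation and solve at this covariance (e.g. the truth,
        for generalized-least-squares comparisons).
    """
    designs = [np.atleast_2d(np.asarray(X, dtype=float)) for X in designs]
    outcomes = [np.atleast_1d(np.asarray(y, dtype=float)) for y in outcomes]
    if len(designs) != len(outcomes):
        raise ShapeError("designs and outcomes must pair up")
    p = designs[0].shape[1]
    n_obs = sum(X.shape[0] for X in designs)
    if n_obs < p:
        raise SingularDesignError("fewer observations than parameters")
    if structure == "unstructured":
        if occasion_grid is None and fixed_working is None:
            raise SpecificationError(
                "unstructured working correlation needs a declared occasion grid"
            )
        if occasion_index is None:
            # balanced shortcut: every cluster covers the full grid
            occasion_index = [list(range(X.shape[0])) for X in designs]

    groups = _group_clusters(designs, outcomes, occasion_index, structure)

    # initial iterate: pooled (independence) least squares
    ident = WorkingCov("independence", None, 1.0)
    XtX, Xty, _, _ = _accumulate(groups, designs, outcomes, None, ident, "independence")
    if np.linalg.cond(XtX) > 1e12:
        raise SingularDesignError("design matrix is (numerically) rank deficient")
    beta = np.linalg.solve(XtX, Xty)

    working = fixed_working
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if fixed_working is None:
            residuals = [y - X @ beta for X, y in zip(designs, outcomes)]
            working = estimate_working(
                residuals, structure, p, occasion_index, occasion_grid
            )
        XtVX, XtVy, _, _ = _accumulate(groups, designs, outcomes, None, working, structure)
        beta_new = np.linalg.solve(XtVX, XtVy)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break
        if fixed_working is not None:
            converged = True  # linear: one solve is exact
            break
    if not converged:
        raise ConvergenceError(
            f"GEE did not converge in {max_iter} iterations", last_iterate=beta, n_iter=it
        )

    XtVX, _, psi, residuals = _accumulate(groups, designs, outcomes, beta, working, structure)
    bread = -XtVX / working.phi
    params = OutcomeParams(beta, list(terms) if terms is not None else [f"b{i}" for i in range(p)])
    return GEEFit(
        params=params,
        working=working,
        score_contributions=psi,
        bread_block=bread,
        n_iter=it,
        converged=True,
        residuals=residuals,
        occasion_index=occasion_index,
    )


def psi_sum(designs, outcomes, beta, working, occasion_index=None):
    """sum_i X_i' V_i^{-1} (y_i - X_i beta) at a fixed working covariance."""
    groups = _group_clusters(designs, outcomes, occasion_index, working.structure)
    _, _, psi, _ = _accumulate(groups, designs, outcomes, np.asarray(beta, float), working, working.structure)
    return psi.sum(axis=0)
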