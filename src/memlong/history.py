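"""Exposure-history functionals and their calibrated expectations.

The outcome model regresses on X(t) = g(exposure history up to t), where g
is one of

``cumulative_average``
    X(t_j) = sum_{k<j} c(t_k) (t_{k+1} - t_k) / (t_j - t_1), a time-weighted
    average of all measurements strictly before t_j (the last weight runs to
    t_j itself).  With equal spacing this is the plain mean of the first
    j - 1 values.
``moving_average``
    mean of available measurements in the closed window [t - b, t].
``cumulative_sum``
    sum of available measurements in the closed window [t - b, t].

Occasions with ``present = False`` never contribute: the cumulative average
re-forms its weights over the available subsequence, and the windowed
functionals average/sum over available points only (the I(s) indicator).

When only the surrogate history C is observed, the conditional expectation
of X given that history is obtained by replacing each pointwise measurement
with its calibrated value f(C, t_mem, W; alpha) from the measurement error
model and applying the same functional (regression calibration).  The MEM
time scale enters f; the outcome time scale forms the weights.  All three
functionals are linear in the pointwise values, so the calibrated history is
exactly linear in alpha.

The first occasion has no strictly-prior history.  ``baseline_rule``
chooses between ``single_value`` (use the first available measurement,
the continuity limit of the cumulative average) and ``exclude`` (the
functional is undefined there and the row is dropped from fitting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, EmptyWindowError, ShapeError

KINDS = ("cumulative_average", "moving_average", "cumulative_sum")
_KIND_ALIASES = {
    "cumavg": "cumulative_average",
    "movavg": "moving_average",
    "cumsum": "cumulative_sum",
}
BASELINE_RULES = ("single_value", "exclude")


@dataclass(frozen=True)
class HistorySpec:
    """Which functional g to apply, and how to treat the first occasion."""

    kind: str = "cumulative_average"
    window: float | None = None
    baseline_rule: str = "single_value"

    def __post_init__(self):
        kind = _KIND_ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in KINDS:
            raise DomainError(f"unknown history kind {self.kind!r}")
        needs_window = kind in ("moving_average", "cumulative_sum")
        if needs_window and (self.window is None or self.window <= 0):
            raise DomainError(f"{kind} requires a positive window")
        if not needs_window and self.window is not None:
            raise DomainError(f"{kind} takes no window")
        if self.baseline_rule not in BASELINE_RULES:
            raise DomainError(f"unknown baseline rule {self.baseline_rule!r}")


@dataclass
class HistoryValue:
    """The functional evaluated at one occasion."""

    t_outcome: float
    value: float
    n_contributing: int


def _split_series(series):
    """Accept (times, values) or (times, values, present) arrays."""
    if len(series) == 2:
        times, values = series
        present = None
    else:
        times, values, present = series
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ShapeError("times and values must have equal length")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DomainError("series times must be strictly increasing")
    if present is None:
        present = np.ones(times.size, dtype=bool)
    else:
        present = np.asarray(present, dtype=bool)
    avail = present & np.isfinite(values)
    return times, values, avail


def history_profile(t_targets, t_avail, v_avail, spec: HistorySpec):
    """Evaluate g at each target time given the available measurements.

    Returns ``(values, counts, defined)`` arrays aligned with ``t_targets``.
    ``defined`` is False where the functional has no value under the spec
    (baseline under ``exclude``, or an empty window).  Vectorised; this is
    the workhorse used by the estimator and the simulator.
    """
    t_targets = np.asarray(t_targets, dtype=float)
    t_avail = np.asarray(t_avail, dtype=float)
    v_avail = np.asarray(v_avail, dtype=float)
    nt = t_targets.size
    values = np.full(nt, np.nan)
    counts = np.zeros(nt, dtype=int)
    defined = np.zeros(nt, dtype=bool)
    if t_avail.size == 0:
        return values, counts, defined

    if spec.kind == "cumulative_average":
        # r = number of available measurements strictly before each target
        r = np.searchsorted(t_avail, t_targets, side="left")
        # prefix[i] = sum_{k<i} v_k (t_{k+1} - t_k) over available points
        gaps = np.diff(t_avail)
        prefix = np.concatenate([[0.0], np.cumsum(v_avail[:-1] * gaps)])
        pos = r > 0
        if np.any(pos):
            rp = r[pos]
            s = prefix[rp - 1] + v_avail[rp - 1] * (t_targets[pos] - t_avail[rp - 1])
            values[pos] = s / (t_targets[pos] - t_avail[0])
            counts[pos] = rp
            defined[pos] = True
        base = ~pos
        if np.any(base) and spec.baseline_rule == "single_value":
            values[base] = v_avail[0]
            counts[base] = 1
            defined[base] = True
    else:
        b = spec.window
        cum = np.concatenate([[0.0], np.cumsum(v_avail)])
        lo = np.searchsorted(t_avail, t_targets - b, side="left")
        hi = np.searchsorted(t_avail, t_targets, side="right")
        n = hi - lo
        ok = n > 0
        s = cum[hi[ok]] - cum[lo[ok]]
        if spec.kind == "moving_average":
            values[ok] = s / n[ok]
        else:
            values[ok] = s
        counts[ok] = n[ok]
        defined[ok] = True
    return values, counts, defined


def _one(series, target_t, spec, *, j=None):
    times, vals, avail = _split_series(series)
    v, c, d = history_profile(
        np.array([target_t]), times[avail], vals[avail], spec
    )
    if not d[0]:
        if spec.kind == "cumulative_average":
            raise DomainError(
                "cumulative average undefined at the first occasion under "
                "baseline_rule='exclude'"
                if j == 1 or not np.any(avail & (times < target_t))
                else "no available history before target"
            )
        raise EmptyWindowError(
            f"no available measurement in [{target_t - spec.window}, {target_t}]"
        )
    return HistoryValue(float(target_t), float(v[0]), int(c[0]))


def cumulative_average(series, j: int, spec: HistorySpec) -> HistoryValue:
    """Time-weighted cumulative average at occasion j (1-based)."""
    if spec.kind != "cumulative_average":
        raise DomainError("spec.kind must be cumulative_average")
    times, _, _ = _split_series(series)
    if not 1 <= j <= times.size:
        raise DomainError(f"occasion index {j} out of range 1..{times.size}")
    if j == 1 and spec.baseline_rule == "exclude":
        raise DomainError("first occasion excluded by baseline rule")
    return _one(series, times[j - 1], spec, j=j)


def moving_average(series, t: float, spec: HistorySpec) -> HistoryValue:
    """Indicator-weighted mean over the closed window [t - b, t]."""
    if spec.kind != "moving_average":
        raise DomainError("spec.kind must be moving_average")
    return _one(series, t, spec)


def cumulative_sum(series, t: float, spec: HistorySpec) -> HistoryValue:
    """Indicator-weighted sum over the closed window [t - b, t]."""
    if spec.kind != "cumulative_sum":
        raise DomainError("spec.kind must be cumulative_sum")
    return _one(series, t, spec)


def calibrated_history(series, j: int, spec: HistorySpec, mem) -> HistoryValue:
    """E[X(t_j) | surrogate history] under a fitted MEM.

    ``series`` is a :class:`~memlong.datamodel.SubjectSeries`; pointwise
    surrogates are replaced by f(C, t_mem, W; alpha) and the functional is
    applied with weights on the outcome time scale.
    """
    from .mem import mem_predict  # local import to avoid a cycle

    avail = series.present & np.isfinite(series.surrogate)
    if mem.n_covariates > series.covariates.shape[1]:
        raise ShapeError(
            f"dataset has {series.covariates.shape[1]} covariates; MEM expects "
            f"{mem.n_covariates}"
        )
    fvals = np.full(series.m, np.nan)
    fvals[avail] = mem_predict(
        mem, series.surrogate[avail], series.t_mem[avail], series.covariates[avail]
    )
    target = series.t_outcome[j - 1]
    if not 1 <= j <= series.m:
        raise DomainError(f"occasion index {j} out of range 1..{series.m}")
    if j == 1 and spec.baseline_rule == "exclude":
        raise DomainError("first occasion excluded by baseline rule")
    return _one((series.t_outcome, fvals, avail), target, spec, j=j)


def subject_history(series, spec: HistorySpec, source="surrogate", mem=None):
    """History values at every occasion of a subject.

    Parameters
    ----------
    source : {"true", "surrogate", "calibrated"}
        Which pointwise values feed the functional.

    Returns ``(values, defined)`` arrays of length ``series.m``; rows with
    ``defined = False`` (excluded baseline, empty window) are dropped from
    downstream fits.
    """
    if source == "true":
        vals = series.true_exposure
    elif source == "surrogate":
        vals = series.surrogate
    elif source == "calibrated":
        if mem is None:
            raise ShapeError("calibrated history needs a fitted MEM")
        from .mem import mem_predict

        avail0 = series.present & np.isfinite(series.surrogate)
        vals = np.full(series.m, np.nan)
        vals[avail0] = mem_predict(
            mem, series.surrogate[avail0], series.t_mem[avail0], series.covariates[avail0]
        )
    else:
        raise DomainError(f"unknown history source {source!r}")
    avail = series.present & np.isfinite(vals)
    values, _, defined = history_profile(
        series.t_outcome, series.t_outcome[avail], vals[avail], spec
    )
    return values, defined


def calibration_matrix(series, spec: HistorySpec, mem_design_fn):
    """Per-subject matrix G with X_hat = G @ alpha.

    Every supported functional is linear in the pointwise calibrated values,
    and the linear MEM predictor is linear in alpha, so the calibrated
    history at each occasion is an exact linear map of alpha.  ``G`` is built
    by pushing each MEM design column through the functional.

    ``mem_design_fn(C, t_mem, W) -> (r, p_alpha)`` builds the MEM design for
    the available occasions.  Returns ``(G, defined)`` with G of shape
    (m, p_alpha) (rows of undefined occasions are NaN).
    """
    avail = series.present & np.isfinite(series.surrogate)
    D = mem_design_fn(series.surrogate[avail], series.t_mem[avail], series.covariates[avail])
    p = D.shape[1]
    G = np.full((series.m, p), np.nan)
    defined = None
    for k in range(p):
        vals, _, dk = history_profile(
            series.t_outcome, series.t_outcome[avail], D[:, k], spec
        )
        G[:, k] = vals
        defined = dk if defined is None else (defined & dk)
    if defined is None:
        defined = np.zeros(series.m, dtype=bool)
    return G, defined
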