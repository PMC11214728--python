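"""Exception hierarchy for memlong.

All package-raised errors derive from :class:`MemlongError` so callers can
distinguish data/model problems from programming errors.
"""


class MemlongError(Exception):
    """Base class for all memlong errors."""


class FormatError(MemlongError):
    """Malformed on-disk data, e.g. duplicate (subject, time) rows."""


class SchemaError(MemlongError):
    """Required columns missing or inconsistent for the requested role."""


class DesignError(MemlongError):
    """Main/validation id sets violate the declared IVS/EVS design."""


class ShapeError(MemlongError):
    """Dimension mismatch between data and a parameter vector."""


class DomainError(MemlongError):
    """A history functional was requested outside its defined domain."""


class EmptyWindowError(DomainError):
    """No available exposure measurement inside the requested time window."""


class SingularDesignError(MemlongError):
    """Rank-deficient design matrix."""


class ConvergenceError(MemlongError):
    """Iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, n_iter=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.n_iter = n_iter


class CalibrationError(MemlongError):
    """A target exposure correlation is unattainable for any noise variance."""


class SpecificationError(MemlongError):
    """Inconsistent model term lists (non-nested comparison, bad terms)."""


class InsufficientDataError(MemlongError):
    """Not enough usable rows for the requested diagnostic."""


class InferenceError(MemlongError):
    """Variance assembly failed (e.g. singular bread matrix)."""
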