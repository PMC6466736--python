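"""Exception hierarchy for pbtest.

All user-facing errors derive from :class:`PBTestError` so callers can catch a
single base class; the subclasses mirror the failure modes of the pipeline
(bad inputs, impossible estimation, degenerate data, numerical breakdown).
"""


class PBTestError(Exception):
    """Base class for all pbtest errors."""


class InvalidInputError(PBTestError, ValueError):
    """Malformed or out-of-range user input (weights, rho, p-values, ...)."""


class InvalidDesignError(PBTestError, ValueError):
    """Design matrix violates a precondition (rank deficiency, size, span)."""


class EstimationError(PBTestError, RuntimeError):
    """Correlation estimation is impossible for the given block structure."""


class DegenerateDataError(PBTestError, RuntimeError):
    """Data carry no usable signal for the requested statistic."""


class DecompositionError(PBTestError, RuntimeError):
    """A matrix decomposition failed (singular, non-symmetric, ill-conditioned)."""


class AlignmentError(PBTestError, ValueError):
    """Sample identifiers do not align across input tables."""
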