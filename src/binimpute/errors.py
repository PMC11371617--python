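"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`BinImputeError`, so callers can catch the package's failures with a
single ``except`` clause while still distinguishing the specific condition.
"""


class BinImputeError(Exception):
    """Base class for all binimpute errors."""


class FormatError(BinImputeError, ValueError):
    """A file does not conform to its declared format."""


class DuplicateRecordError(FormatError):
    """Two records carry the same timestamp."""


class AlignmentError(BinImputeError, ValueError):
    """Timestamps, gaps, or durations are not aligned to the sampling grid."""


class ResampleError(AlignmentError):
    """Target step is not an integer multiple of the source step."""


class ConfigurationError(BinImputeError, ValueError):
    """An option value is invalid (unknown channel, bad bin size, ...)."""


class InsufficientDataError(BinImputeError, ValueError):
    """Fewer eligible days (or rows) than requested."""


class PreconditionError(BinImputeError, ValueError):
    """A documented operation precondition does not hold."""


class DegenerateColumnError(BinImputeError, ValueError):
    """A column has no observed value to impute from."""


class NumericalError(BinImputeError, ArithmeticError):
    """A linear-algebra step failed (singular system, non-PD covariance)."""


class ContractError(BinImputeError, ValueError):
    """Caller violated an interface contract (length mismatch, missing records)."""
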