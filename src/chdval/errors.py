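"""Exception hierarchy shared across the package."""


class ChdvalError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ChdvalError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(ChdvalError, ValueError):
    """A cohort table does not match the expected column schema."""


class ConfigurationError(ChdvalError, ValueError):
    """A configuration object is internally inconsistent."""


class DegenerateGroupingError(ChdvalError, ValueError):
    """Risk groups cannot be formed (too few distinct predictions, or a
    group with predicted risk exactly 0 or 1)."""


class ImputationError(ChdvalError, ValueError):
    """A variable cannot be imputed (e.g. 100% missing)."""


class ConvergenceError(ChdvalError, RuntimeError):
    """An iterative fit failed to converge; diagnostics in ``args``."""


class UndefinedResultError(ChdvalError, ValueError):
    """The requested statistic is undefined on these data (e.g. a
    concordance index with no usable pairs)."""
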