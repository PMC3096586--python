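"""Exception hierarchy shared across the package."""


class PTimeboxError(Exception):
    """Base class for all package-specific errors."""


class MatrixFormatError(PTimeboxError, ValueError):
    """A matrix file is syntactically malformed (ragged rows, bad numbers)."""


class ValidationError(PTimeboxError, ValueError):
    """A domain object violates its invariants."""


class QueryValidationError(ValidationError):
    """A timebox query violates the query consistency constraints."""


class EmptyFilterError(ValidationError):
    """Filtering removed every time course."""


class CompileError(PTimeboxError, ValueError):
    """A query cannot be compiled into a linear HMM."""
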