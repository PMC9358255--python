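"""Exception hierarchy shared across the package."""


class DFNCKitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DFNCKitError, ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateWindowError(DFNCKitError, ValueError):
    """Raised when a sliding window contains a zero-variance component.

    Correlation is undefined for a constant signal, and silently emitting
    NaN would poison every downstream clustering step, so this is a hard
    error identifying the subject, window and component involved.
    """


class DegenerateDataError(DFNCKitError, ValueError):
    """Raised when a statistic is undefined for the given data
    (e.g. Pearson correlation of a zero-variance vector)."""


class SchemaError(DFNCKitError, ValueError):
    """Raised when a persisted container does not match the expected schema."""
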