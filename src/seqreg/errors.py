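"""Exception hierarchy shared across the package."""


class SeqregError(Exception):
    """Base class for all package errors."""


class SchemaError(SeqregError):
    """Input table does not match the declared block ordering."""


class EmptyInputError(SeqregError):
    """A table or vector with no usable rows was supplied."""


class IdentificationError(SeqregError):
    """A variable name is unknown to the ordering or graph."""


class DomainError(SeqregError):
    """A value lies outside the mathematical domain of an operation."""


class StateError(SeqregError):
    """An operation was applied in an invalid object state."""


class InsufficientDataError(SeqregError):
    """Too few observations for the requested computation."""


class CollinearityError(SeqregError):
    """Design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class DegenerateDataError(SeqregError):
    """Residuals or inputs have zero variance where variability is required."""


class ValidityError(SeqregError):
    """A structural object violates its own invariants."""


class CalibrationError(SeqregError):
    """Noise calibration target cannot be attained."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
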