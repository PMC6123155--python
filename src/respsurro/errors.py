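"""Exception hierarchy shared by all pipeline stages."""


class RespSurroError(Exception):
    """Base class for all package errors."""


class ParameterError(RespSurroError):
    """A parameter violates its documented invariant.

    Deliberately not a ValueError: pydantic would otherwise swallow it into a
    ValidationError during model construction.
    """


class TraceValidationError(RespSurroError, ValueError):
    """A trace (or pair of traces) fails structural validation."""


class ParseError(RespSurroError, ValueError):
    """A surrogate file could not be parsed.

    Carries the 1-based line number when the offending line is known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StateError(RespSurroError, RuntimeError):
    """An object lacks state required by the requested operation."""


class DegenerateInputError(RespSurroError, ValueError):
    """Input is degenerate for the operation (constant trace, no overlap, ...)."""


class InsufficientDataError(RespSurroError, ValueError):
    """Not enough cycles/extrema/samples to compute the requested quantity."""


class PairingError(RespSurroError, ValueError):
    """Two traces' cycles could not be matched one-to-one."""


class DataInsufficiencyError(RespSurroError, ValueError):
    """A (couch position, phase) cell has no candidate frame."""


class FitError(RespSurroError, ValueError):
    """Model fitting failed (degenerate or collinear data)."""
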