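"""Exception hierarchy.

All parameter/contract violations raise subclasses of :class:`CngError`
(itself a ``ValueError``) so callers can catch one family.
"""


class CngError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(CngError):
    """A scalar argument or model parameter is outside its admissible range."""


class ProtocolError(CngError):
    """A voltage protocol could not be constructed or is inconsistent."""


class AlignmentError(CngError):
    """Two recordings/curves that must share structure (sweep count, V grid) do not."""


class NormalizationError(CngError):
    """A normalization anchor (e.g. the +200 mV point) is missing."""


class FitError(CngError):
    """A curve fit failed to converge from every starting point."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class AtfParseError(CngError):
    """An Axon-Text-File could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
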