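"""Exception hierarchy for the toolkit."""


class SoxkinError(Exception):
    """Base class for all package errors."""


class TraceFormatError(SoxkinError):
    """A trace/spectrum/table file violates the documented CSV dialect."""


class ValidationError(SoxkinError):
    """A value violates a domain invariant (e.g. lifetime <= 0)."""


class InsufficientDataError(SoxkinError):
    """Too few bins/points for the requested operation."""


class FitError(SoxkinError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NumericalError(SoxkinError):
    """The PDE solver produced an unusable solution (instability etc.)."""
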