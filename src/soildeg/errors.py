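"""Exception hierarchy shared across the package.

All physically-impossible or out-of-contract inputs raise
:class:`InvalidInputError` (a ``ValueError``), so callers can catch one type
regardless of which stage rejected the data.
"""


class SoildegError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SoildegError, ValueError):
    """An input violates a documented precondition."""


class RangeError(InvalidInputError):
    """A value falls outside the validity range of a model or forcing."""


class InconsistentSampleError(InvalidInputError):
    """A physical sample is self-contradictory (e.g. negative porosity)."""


class MeasurementError(SoildegError):
    """A raw measurement is outside what instrument noise can explain."""


class IllPosedFitError(SoildegError):
    """The data cannot identify the model parameters (e.g. no interior maximum)."""


class FitConvergenceError(SoildegError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


class SchemaError(SoildegError):
    """A delimited-text dataset does not match its declared schema."""

    def __init__(self, message: str, lines: list[str] | None = None):
        super().__init__(message)
        self.lines = lines or []
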