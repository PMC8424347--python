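"""Exception hierarchy."""


class ArtmechError(Exception):
    """Base class for all package errors."""


class DomainError(ArtmechError, ValueError):
    """A physical or structural parameter is outside its admissible range."""


class NumericRangeError(ArtmechError, FloatingPointError):
    """A computation left the representable floating-point range
    (e.g. overflow of the exponential fibre term)."""


class SolverError(ArtmechError, RuntimeError):
    """The uniaxial equilibrium root-find failed; carries diagnostic state."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(ArtmechError, RuntimeError):
    """Least-squares parameter identification failed; may carry the best
    partial result."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class UndefinedStatisticError(ArtmechError, ZeroDivisionError):
    """A summary statistic (e.g. R^2 with zero total variance) is undefined."""
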