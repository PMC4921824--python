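"""Exception hierarchy for oligoeq."""


class OligoeqError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OligoeqError, ValueError):
    """A thermodynamic or model parameter is out of its valid domain."""


class SupersaturationError(OligoeqError, ValueError):
    """K*m >= 1: the isodesmic series diverges for this free monomer level."""


class ConvergenceError(OligoeqError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    Carries solver diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SchemeMismatchError(OligoeqError, ValueError):
    """Labelling scheme is incompatible with the supplied equilibrium state."""


class UndefinedCompositionError(OligoeqError, ValueError):
    """Composition fractions requested for a state with no dimers at all."""


class FitError(OligoeqError, RuntimeError):
    """Model fitting failed (degenerate data, no signal, etc.)."""


class DataValidationError(OligoeqError, ValueError):
    """A measurement table violates the input schema; row context included."""
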