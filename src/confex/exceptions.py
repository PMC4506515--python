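"""Exception hierarchy shared across fitting modules."""


class ConfexError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ConfexError, ValueError):
    """Input violates a structural precondition (shapes, counts, ordering)."""


class DomainError(ConfexError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. T <= 0)."""


class FitFailureError(ConfexError, RuntimeError):
    """A nonlinear fit failed to converge or the data carry no signal."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class OutOfRegimeError(ConfexError, ValueError):
    """Data fall outside the validity regime of an estimator."""


class IdentifiabilityError(ConfexError, ValueError):
    """Model parameters cannot be distinguished by the supplied data."""


class ConfigError(ConfexError, ValueError):
    """Pipeline configuration is malformed or inconsistent."""
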