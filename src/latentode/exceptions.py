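"""Exception hierarchy shared across the package."""


class LatentODEError(Exception):
    """Base class for all package errors."""


class InvalidModelError(LatentODEError):
    """A network model violates its structural contract (shape, sign, ...)."""


class ConfigurationError(LatentODEError):
    """An unknown option value or an inconsistent configuration."""


class IntegrationError(LatentODEError):
    """The ODE solver failed; ``time`` holds the failure time when known."""

    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


class DomainError(LatentODEError):
    """Evaluation requested outside the domain of a fitted object."""


class FittingError(LatentODEError):
    """A spline or likelihood fit could not be computed."""


class InvalidWeightsError(LatentODEError):
    """An all-zero or otherwise unusable latent weight vector."""


class InvalidSupportError(LatentODEError):
    """A candidate support contains components that cannot carry a weight."""


class AlignmentError(LatentODEError):
    """Two time grids that must coincide do not."""


class ParseError(LatentODEError):
    """Malformed tabular input; ``row``/``column`` locate the offence."""

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class UndefinedError(LatentODEError):
    """A quantity is undefined for the given (typically empty) input."""
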