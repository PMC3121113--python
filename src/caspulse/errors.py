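"""Exception hierarchy shared across the package."""


class CaspulseError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CaspulseError, ValueError):
    """An argument violates a documented precondition (e.g. negative concentration)."""


class ConfigurationError(CaspulseError, ValueError):
    """A config file could not be parsed or contains an unknown/invalid key."""


class NumericalFailureError(CaspulseError, RuntimeError):
    """An iterative numerical procedure failed to converge.

    Carries whatever diagnostic the caller attached (residual norm, bracket
    values, time of failure) in ``details``.
    """

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.details = details


class LogicError(CaspulseError, RuntimeError):
    """Internal contract violation, e.g. querying history beyond computed time."""


class FlaggedResultWarning(UserWarning):
    """A result is returned but inconsistent with model expectations.

    Used when a cross-check (closed form vs finite difference) disagrees
    beyond tolerance, or a resistance coefficient comes out negative.
    """
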