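"""Exception hierarchy shared across the package."""

from __future__ import annotations


class QbifError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(QbifError, ValueError):
    """An argument violates a documented precondition."""


class ConvergenceError(QbifError, RuntimeError):
    """Iterative fit failed to converge.

    Carries the last iterate so callers can inspect or salvage it.
    """

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class DegenerateFitError(QbifError, RuntimeError):
    """Fitted coefficients cannot be mapped back to SII parameters
    (all per-band slopes non-positive)."""


class NumericalStateError(QbifError, RuntimeError):
    """A posterior state is numerically invalid (e.g. covariance not
    positive definite)."""


class ConfigError(QbifError, ValueError):
    """A configuration file or value failed validation."""


class SessionAbortedError(QbifError, RuntimeError):
    """The response callback raised; carries the partial session result."""

    def __init__(self, message: str, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result
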