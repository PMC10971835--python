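"""Exception hierarchy for hollowfiber."""


class HollowFiberError(Exception):
    """Base class for all package errors."""


class ConfigError(HollowFiberError):
    """Malformed or incomplete configuration file."""


class ValidationError(HollowFiberError):
    """A case record violates one of its invariants."""


class DomainError(HollowFiberError):
    """An argument lies outside the physical domain of an operation."""


class GridError(HollowFiberError):
    """Invalid grid construction request."""


class SolverError(HollowFiberError):
    """A solver failed to converge; carries residual history when available."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class PreconditionError(HollowFiberError):
    """An operation received an unconverged or inconsistent input field."""
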