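"""Exception hierarchy shared across the package."""


class ProtomixError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ProtomixError, ValueError):
    """Invalid generator or fitting configuration."""


class GenerationError(ProtomixError, RuntimeError):
    """Stimulus rejection sampling exhausted its attempt budget."""


class ParseError(ProtomixError, ValueError):
    """Malformed stimulus or data file."""


class DataError(ProtomixError, ValueError):
    """Degenerate or inconsistent behavioural data."""


class InitializationError(ProtomixError, RuntimeError):
    """No finite-likelihood starting point could be found for MCMC."""


class DiagnosticError(ProtomixError, ValueError):
    """Convergence diagnostic requested on inadequate draws."""


class SelectionError(ProtomixError, RuntimeError):
    """Model selection impossible (e.g. no converged fits)."""


class QCError(ProtomixError, ValueError):
    """Participant quality control could not be evaluated."""


class StateError(ProtomixError, RuntimeError):
    """Illegal transition of the training protocol state machine."""


class UndefinedCorrelationError(ProtomixError, ValueError):
    """Correlation requested on a zero-variance vector."""
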