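"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`SmcriskError`
so callers (and the CLI) can map error families to exit codes.
"""


class SmcriskError(Exception):
    """Base class for all smcrisk errors."""


class InvalidInputError(SmcriskError, ValueError):
    """An argument violates a documented precondition (sign, range, shape)."""


class DegenerateSchemaError(InvalidInputError):
    """A severity schema whose cost-weighted counts are all zero."""


class IncompleteTableError(InvalidInputError):
    """An evidence table with a missing (factor, class) cell."""


class InvalidOverrideError(InvalidInputError):
    """An expert override that breaks positivity or references unknown labels."""


class MissingRandomIndexError(InvalidInputError):
    """Matrix order outside the random-index table without the extension flag."""


class ConvergenceError(SmcriskError, RuntimeError):
    """Power iteration hit the iteration limit; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class OptimizationError(SmcriskError, RuntimeError):
    """A BWM/FUCOM solver failed; carries the best residual seen."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class IncompleteHierarchyError(SmcriskError, ValueError):
    """A hierarchy node is missing local weights before synthesis."""


class ConsistencyError(SmcriskError):
    """A PCM failed the CR < 0.10 rule under strict consistency checking."""


class ConfigError(SmcriskError, ValueError):
    """A study configuration that does not parse or references missing files."""
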