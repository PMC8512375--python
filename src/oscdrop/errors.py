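"""Exception hierarchy.

All package errors derive from :class:`OscdropError` so callers can catch one
type at the CLI boundary; the subclasses distinguish configuration mistakes
from data/measurement problems and from numerical failures.
"""


class OscdropError(Exception):
    """Base class for all oscdrop errors."""


class ConfigurationError(OscdropError, ValueError):
    """A parameter or config value is invalid (bad span, unknown key, ...)."""


class TraceError(OscdropError, ValueError):
    """A trace violates its invariants (non-monotone time, too short, ...)."""


class ParseError(OscdropError, ValueError):
    """A file does not conform to the expected CSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PrecisionError(OscdropError, ValueError):
    """The data cannot support the requested analysis (too few periods)."""


class SamplingError(OscdropError, ValueError):
    """Requested frequency content is not representable at the sample rate."""


class NoExcitationError(OscdropError, ValueError):
    """The drop-area oscillation amplitude is below the detectability floor."""


class InsufficientDataError(OscdropError, ValueError):
    """Not enough points to constrain a fit."""


class ConvergenceError(OscdropError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (last residual {residual:.3e})"
        super().__init__(message)
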