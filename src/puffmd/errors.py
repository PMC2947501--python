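"""Exception hierarchy for puffmd.

Every error raised by the package derives from :class:`PuffError` so callers
can catch the package's failures in one clause.  Errors that signal bad user
input additionally derive from :class:`ValueError`.
"""


class PuffError(Exception):
    """Base class for all puffmd errors."""


class InvalidArgumentError(PuffError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDofError(InvalidArgumentError):
    """Too few degrees of freedom for the requested statistic."""


class SingularGeometryError(PuffError):
    """Two bonded particles coincide; the bond direction is undefined."""


class IntegrationBlowupError(PuffError):
    """Non-finite forces or coordinates encountered during integration."""

    def __init__(self, message: str, particle: int | None = None):
        super().__init__(message)
        self.particle = particle


class DegenerateAxisError(PuffError):
    """The two anchor-group centres of mass coincide."""


class InsufficientDataError(PuffError, ValueError):
    """Not enough samples for the requested analysis."""


class InvalidCutoffError(InvalidArgumentError):
    """Low-pass cutoff shorter than two samples."""


class BoundaryNotBracketedError(PuffError):
    """A velocity sweep contains no trapped-to-unimpeded transition."""


class RestartParseError(PuffError):
    """Malformed restart file; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class SchemaVersionError(PuffError):
    """Pulse-log schema major version does not match this package."""


class ConfigError(PuffError, ValueError):
    """Run configuration failed validation; message names the field path."""
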