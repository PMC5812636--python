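"""Exception hierarchy.

Validation and configuration problems raise :class:`ValidationError` (or a
subclass); file-format and I/O problems raise :class:`FormatError` /
``OSError``.  The CLI maps the former to exit code 2 and the latter to 3.
"""


class MyofuseError(Exception):
    """Base class for all package errors."""


class ValidationError(MyofuseError, ValueError):
    """Input violates a documented precondition or invariant."""


class DimensionError(ValidationError):
    """Array or image shapes are incompatible."""


class ConfigError(ValidationError):
    """Inconsistent or incomplete configuration."""


class FormatError(MyofuseError, OSError):
    """A file exists but is not in the expected format."""


class EmptyResultError(ValidationError):
    """A writer was handed no results."""


class UndefinedIndexError(ValidationError):
    """Fusion index requested for a scene without any nuclei."""


class ReconciliationError(ValidationError):
    """Per-scene results could not be matched against a plate manifest."""


class InsufficientReplicationError(ValidationError):
    """Too few conditions or replicates for the requested statistical test."""


class SimulationError(MyofuseError, RuntimeError):
    """Scene synthesis failed, e.g. object placement exceeded the retry cap."""


class StageError(MyofuseError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
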