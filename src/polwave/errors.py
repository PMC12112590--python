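"""Exception hierarchy for polwave.

Every error raised deliberately by the package derives from
:class:`PolwaveError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""

from __future__ import annotations


class PolwaveError(Exception):
    """Base class for all polwave errors."""


class ParameterError(PolwaveError, ValueError):
    """A numeric or structural parameter violates its contract."""


class ParseError(PolwaveError, ValueError):
    """An input file could not be parsed; message names the offending line."""


class FormatError(PolwaveError, ValueError):
    """An input file parsed but violates format-level invariants."""


class LayoutError(PolwaveError):
    """Synthetic genes could not be placed without overlap."""


class EstimationError(PolwaveError):
    """Not enough valid data to estimate the requested quantity."""


class ConfigError(PolwaveError):
    """Run configuration is invalid; carries the full violation list."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class StageError(PolwaveError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
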