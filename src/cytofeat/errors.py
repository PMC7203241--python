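"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class CytofeatError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(CytofeatError):
    """Panel/config and input files disagree, or a config value is invalid."""


class GateError(CytofeatError):
    """A cleaning gate cannot be fit on the given events."""


class NoValleyError(GateError):
    """The kernel density estimate has no interior valley between two modes.

    Carries the location of the single dominant mode so callers can fall
    back to a quantile rule or report the offending channel.
    """

    def __init__(self, message: str, mode_location: float | None = None):
        super().__init__(message)
        self.mode_location = mode_location
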