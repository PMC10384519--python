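"""Exception hierarchy.

Everything raised on bad user input derives from :class:`EnosecastError`
(itself a ``ValueError``) so callers can catch one type at the boundary.
"""


class EnosecastError(ValueError):
    """Base class for all domain errors raised by this package."""


class ConfigError(EnosecastError):
    """A configuration object violates one of its invariants."""


class ParameterError(EnosecastError):
    """An operation argument is outside its documented domain."""


class RangeError(EnosecastError):
    """A concentration lies outside the sensor's measuring range."""


class BoundsError(EnosecastError):
    """A day or horizon index falls outside the simulated span."""


class SchemaError(EnosecastError):
    """A CSV file does not match the expected dialect/header."""


class EmptySessionError(EnosecastError):
    """A session file contains a header but no samples."""


class NotStabilizedError(EnosecastError):
    """A channel's signal never satisfied the stability rule."""

    def __init__(self, channel: str, message: str | None = None):
        self.channel = channel
        super().__init__(message or f"channel {channel!r} did not stabilize")


class DivergenceError(EnosecastError):
    """Gradient training produced a non-finite loss."""


class ObjectiveError(EnosecastError):
    """An optimization objective returned a non-finite value."""


class InsufficientDataError(EnosecastError):
    """A series is too short for the requested window structure."""


class DegenerateVarianceError(EnosecastError):
    """R^2 is undefined because the targets have zero variance."""


class DegenerateLabelError(EnosecastError):
    """A classification dataset contains a single class only."""
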