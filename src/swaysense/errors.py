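"""Exception hierarchy shared across the package.

Every error raised by swaysense derives from :class:`SwaySenseError`, so
callers (and the CLI, which maps validation failures to exit code 2 and
degenerate cohorts to exit code 3) can catch one base class.
"""


class SwaySenseError(Exception):
    """Base class for all swaysense errors."""


class ValidationError(SwaySenseError):
    """Invalid configuration, parameter, or value (CLI exit code 2)."""


class UndefinedOrientationError(ValidationError):
    """Tilt requested for an (exactly) zero acceleration vector.

    Orientation is undefined in free fall: there is no gravity direction
    to measure against.
    """


class SamplingError(ValidationError):
    """Timestamps are irregular beyond the configured tolerance."""


class ConfigError(ValidationError):
    """Inconsistent run configuration (e.g. tilt rate not a divisor)."""


class ParseError(ValidationError):
    """Malformed input file (bad rows, non-monotone time, range violations)."""


class RangeError(ParseError):
    """Acceleration value outside the sensor's full scale (±8 G)."""


class EmptySeriesError(ValidationError):
    """An operation that needs data received an empty series."""


class InsufficientDataError(ValidationError):
    """Trial too short for the requested windowing (needs ≥ 3 s)."""


class DataError(ValidationError):
    """A subject record is missing a field required by the active criterion."""


class DegenerateCohortError(SwaySenseError):
    """Only one class present under the active criterion (CLI exit code 3)."""
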