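"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`legdose.cli`.
"""


class LegdoseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LegdoseError):
    """A file does not follow the documented on-disk format."""


class ValidationError(LegdoseError):
    """Data or parameters violate a documented invariant."""


class ConfigurationError(ValidationError):
    """A run configuration or protocol specification is unusable."""


class SchedulingError(LegdoseError):
    """Week schedule entries overlap or fall outside the week."""


class CalibrationError(LegdoseError):
    """A calibration session does not meet the preconditions for dosing."""


class OutOfRangeError(LegdoseError):
    """A timestamp or window falls outside the available data."""
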