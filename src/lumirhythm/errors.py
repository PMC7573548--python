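"""Exception hierarchy.

Every failure mode raised by this package derives from :class:`LumirhythmError`
so callers can catch the package's errors without masking programming bugs.
"""


class LumirhythmError(Exception):
    """Base class for all errors raised by lumirhythm."""


class PlateFormatError(LumirhythmError):
    """A plate file violates the wide-CSV dialect (non-numeric cell,
    non-monotone time, duplicate column, wrong header)."""


class PlateConfigError(LumirhythmError):
    """Metadata does not line up with the plate (missing or extraneous well,
    missing sidecar)."""


class TraceLengthError(LumirhythmError):
    """A trace is too short for the requested operation."""


class ParameterError(LumirhythmError):
    """An out-of-range or inconsistent parameter; the message names the field."""


class FitNumericalError(LumirhythmError):
    """The least-squares design was rank deficient (e.g. aliasing at a period
    close to twice the sampling interval)."""


class ConditionNotFoundError(LumirhythmError, LookupError):
    """A condition label is absent from the plate metadata."""


class AggregationError(LumirhythmError):
    """Summary statistics requested over an empty collection."""
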