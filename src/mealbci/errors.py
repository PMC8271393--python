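"""Exception hierarchy shared across the pipeline."""


class MealBciError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MealBciError, ValueError):
    """A parameter combination is invalid (overlapping windows, bad durations...)."""


class SamplingError(MealBciError, ValueError):
    """A frequency violates the sampling theorem for the given rate."""


class NamedChannelError(MealBciError, KeyError):
    """A required channel label is absent from a recording."""


class FormatError(MealBciError, ValueError):
    """A file could not be parsed as the expected recording format."""


class CalibrationError(MealBciError, ValueError):
    """A calibration signal contains no usable activity."""


class SequencingError(MealBciError, ValueError):
    """Events arrived out of temporal order."""
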