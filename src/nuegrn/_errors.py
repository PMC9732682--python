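"""Exception hierarchy shared across the pipeline stages."""


class NuegrnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NuegrnError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(NuegrnError, ValueError):
    """Malformed or degenerate input data."""


class UndefinedRatioError(DataError):
    """A ratio whose denominator is zero or negative where positivity is required."""
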