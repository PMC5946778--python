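"""Exception hierarchy shared across the package."""


class LightsweepError(Exception):
    """Base class for package errors."""


class ConfigError(LightsweepError, ValueError):
    """Invalid configuration or parameter value.

    Raised when a user-supplied parameter violates its contract
    (non-positive radius, exposure not matching the scan period, ...).
    The message names the offending field.
    """


class DataError(LightsweepError, ValueError):
    """Malformed or unusable input data (ROI outside frame, negative F0, ...)."""
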