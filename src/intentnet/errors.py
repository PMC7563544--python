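"""Exception types shared across the package."""


class IntentNetError(Exception):
    """Base class for all intentnet errors."""


class ConfigError(IntentNetError, ValueError):
    """Raised when a configuration value is invalid (rates, bands, ranges)."""


class InsufficientDataError(IntentNetError, ValueError):
    """Raised when an operation receives fewer samples/trials than it needs."""


class RateMismatchError(IntentNetError, ValueError):
    """Raised when two series that must share a sampling rate do not."""
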