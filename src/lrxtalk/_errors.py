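"""Exception hierarchy shared across the package."""


class LRxTalkError(Exception):
    """Base class for all package errors."""


class ConfigError(LRxTalkError):
    """Invalid configuration or missing required parameters."""


class DataError(LRxTalkError):
    """Invalid, inconsistent, or degenerate input data."""
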