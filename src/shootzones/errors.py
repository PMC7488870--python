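"""Package exceptions, mapped to CLI exit codes (config=2, data=3)."""


class ShootzonesError(Exception):
    """Base class for package errors."""


class ConfigError(ShootzonesError):
    """Invalid configuration or model structure."""


class DataError(ShootzonesError):
    """Invalid or inconsistent input data."""
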