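"""Exception types shared across the package."""


class EmulsimError(Exception):
    """Base class for all package errors."""


class ConfigError(EmulsimError):
    """Invalid configuration (bad value, unknown key, overlapping windows)."""


class DataError(EmulsimError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file does not conform to the expected tabular format."""
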