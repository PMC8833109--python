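"""Exception types shared across the package."""


class OmiclocksError(Exception):
    """Base class for package errors."""


class ConfigError(OmiclocksError):
    """Invalid configuration (bad parameter values, malformed config file)."""


class DataError(OmiclocksError):
    """Data unsuitable for the requested operation (missing columns,
    too few complete rows, too few events, unidentifiable model)."""
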