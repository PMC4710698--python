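"""Exception hierarchy shared across the pipeline stages."""


class PbArrayError(Exception):
    """Base class for all package errors."""


class DataError(PbArrayError):
    """Malformed or invalid input data (nonpositive intensity, duplicate ids, ...)."""


class ParameterError(PbArrayError):
    """Invalid configuration or operation parameter; names the offending field."""


class ConfigError(ParameterError):
    """Invalid pipeline configuration file (unknown key, out-of-range threshold)."""
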