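"""Exception types shared across the pipeline."""


class MorbnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MorbnetError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class DataError(MorbnetError, ValueError):
    """An input table violates a schema or value constraint."""
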