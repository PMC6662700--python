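"""Package exceptions."""


class EetolabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EetolabError, ValueError):
    """A configuration value violates its contract (ranges, counts, geometry)."""


class SchemaError(EetolabError, ValueError):
    """A table is missing required columns or has incompatible dtypes."""
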