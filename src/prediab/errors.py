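"""Exception types shared across the pipeline."""


class PrediabError(Exception):
    """Base class for package errors."""


class ConfigError(PrediabError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(PrediabError):
    """Input table is missing required columns or is structurally unreadable."""
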