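"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class MissingConditionError(KeyError):
    """A requested experimental condition is absent from a cell table."""
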