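"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input violates a precondition of an analysis operation."""


class ConfigurationError(ValueError):
    """A configuration value (color key, filter band, window) is invalid."""
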