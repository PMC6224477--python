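"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter violates its documented domain."""


class ConfigError(ValueError):
    """A configuration file is malformed; the message names the offending key."""
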