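"""Exception hierarchy shared across the toolkit."""


class TboneError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TboneError):
    """A file does not conform to its declared format.

    Where possible the message names the offending line number.
    """


class ValidationError(TboneError):
    """A record violates a domain invariant (coordinates, alphabet, ...)."""


class ParameterError(TboneError):
    """A parameter value is outside its documented domain."""


class ConfigError(TboneError):
    """A pipeline or simulation configuration is inconsistent."""
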