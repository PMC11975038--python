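"""Exception hierarchy for agevelo."""


class AgeVeloError(Exception):
    """Base class for all agevelo errors."""


class ConfigError(AgeVeloError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(AgeVeloError):
    """Malformed or inconsistent on-disk data; the message locates the problem."""


class DomainError(AgeVeloError):
    """Input outside the mathematical domain of an operation."""
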