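class ExonweaverError(Exception):
    """Base class for package errors."""


class ConfigurationError(ExonweaverError, ValueError):
    """Invalid parameter or penalty configuration."""


class InvalidParseError(ExonweaverError, ValueError):
    """A segment pair violates its category invariant, so no penalty is defined."""


class InputError(ExonweaverError, ValueError):
    """Malformed or unusable input data."""
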