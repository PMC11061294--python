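"""Exception types shared across the package."""


class Ct5hmcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(Ct5hmcError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(Ct5hmcError):
    """Input data violate a precondition (shape, range, vocabulary)."""
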