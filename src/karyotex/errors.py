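"""Exception hierarchy used across the package."""


class KaryotexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KaryotexError):
    """A parameter or configuration value is outside its documented range."""


class FormatError(KaryotexError):
    """An input file or array does not have the expected layout."""


class ValidationError(KaryotexError):
    """Input data violate a documented precondition or invariant."""
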