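"""Exception hierarchy shared across the package."""


class CropstackError(Exception):
    """Base class for all package errors."""


class ValidationError(CropstackError, ValueError):
    """Raised when a value, record, or configuration violates an invariant."""


class ParseError(CropstackError, ValueError):
    """Raised when an input file cannot be parsed into the expected schema."""


class CoverageError(ValidationError):
    """Raised when the knowledge base does not cover the labels being trained on."""
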