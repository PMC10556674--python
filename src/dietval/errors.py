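"""Exception hierarchy shared across the package."""


class DietvalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DietvalError):
    """A table is missing a required column or has an unusable header."""


class ParseError(DietvalError):
    """A field could not be parsed; message carries the 1-based row number."""


class ValidationError(DietvalError):
    """A value violates a domain constraint (e.g. an unknown occasion label)."""


class DomainError(DietvalError, ValueError):
    """An input is outside the mathematical domain of an operation."""
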