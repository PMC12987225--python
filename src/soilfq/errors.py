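"""Exception hierarchy shared by all soilfq modules."""


class SoilFQError(Exception):
    """Base class for all package errors."""


class SchemaError(SoilFQError):
    """A table is missing a required column or has an unknown schema."""


class ParseError(SoilFQError):
    """A cell could not be converted to the declared type."""


class ValidationError(SoilFQError):
    """A record violates a declared invariant; the message names the field."""


class DomainError(SoilFQError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ExtrapolationError(DomainError):
    """A reference soil mass exceeds the mass actually present in a profile."""
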