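"""Exception types raised by scatcomp readers and analyses."""


class ScatcompError(Exception):
    """Base class for all scatcomp errors."""


class SchemaError(ScatcompError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(ScatcompError, ValueError):
    """Row-level content violates a documented invariant (bad label, bad value)."""
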