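"""Exception hierarchy shared across the pipeline."""


class LomasError(Exception):
    """Base class for all package errors."""


class SchemaError(LomasError):
    """Input table is missing a required column or has an unusable header."""


class ValidationError(LomasError):
    """A record violates a data invariant (negative count, duplicate key, ...)."""


class UndefinedIndexError(LomasError):
    """An index is mathematically undefined for the given inputs
    (e.g. IVI with zero total cover, SI with a zero humid-month value)."""


class AmbiguityError(LomasError):
    """More than one candidate campaign matches a seasonal window."""
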