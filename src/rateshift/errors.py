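"""Exception hierarchy shared across the pipeline."""


class RateshiftError(Exception):
    """Base class for all package errors."""


class NewickParseError(RateshiftError):
    """Malformed Newick input; message names the offending position."""


class ValidationError(RateshiftError):
    """An input violates a documented invariant."""


class InsufficientDataError(RateshiftError):
    """Too few usable observations for the requested computation."""


class UndefinedValueError(RateshiftError):
    """The requested quantity is undefined for this input (e.g. no
    comparable alignment columns)."""
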