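"""Exception hierarchy shared across the package."""


class DffoctError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DffoctError, ValueError):
    """Input data violates a precondition (shape, finiteness, emptiness)."""


class InvalidParameterError(DffoctError, ValueError):
    """A parameter value is outside its allowed range."""


class DegenerateInputError(DffoctError, ValueError):
    """Input is too degenerate for the operation (e.g. too few distinct levels)."""


class FormatError(DffoctError, ValueError):
    """A file on disk is not in the expected format."""
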