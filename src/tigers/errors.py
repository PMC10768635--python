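"""Exception hierarchy shared across the package."""


class TigersError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TigersError):
    """A file did not conform to its declared format."""


class DataError(TigersError):
    """Input data violated a precondition (labels, shapes, emptiness)."""


class NumericError(TigersError):
    """A numeric computation failed (divergence, undefined denominator)."""
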