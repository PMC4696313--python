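"""Exception types shared across the package."""


class PositivityError(ValueError):
    """Raised when data that must be strictly positive contains a value <= 0.

    Normalized Shannon entropy and the log-transform used by the
    Fligner-Killeen test are undefined on zero or negative values.
    """


class AlignmentError(ValueError):
    """Raised when the two condition matrices do not carry identical row
    labels in identical order."""


class MatrixParseError(ValueError):
    """Raised when a matrix file contains a malformed cell or duplicate
    row labels."""
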