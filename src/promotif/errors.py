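"""Exception hierarchy shared across the package.

``ValidationError`` covers bad user input (malformed files, out-of-range
parameters); ``MotifFormatError`` is its specialisation for JASPAR text.
The CLI maps ``ValidationError`` to exit code 2 and anything else to 1.
"""


class PromotifError(Exception):
    """Base class for all package errors."""


class ValidationError(PromotifError, ValueError):
    """Invalid input data or parameter value."""


class MotifFormatError(ValidationError):
    """Malformed JASPAR PFM text."""
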