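"""Exception types shared across the package."""


class CrossBetaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrossBetaError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CrossBetaError, ValueError):
    """The input model does not contain enough structure for the operation."""


class ParseError(CrossBetaError, ValueError):
    """A coordinate file could not be parsed."""


class EmptyInputError(CrossBetaError, ValueError):
    """A coordinate file contained no atoms."""
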