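"""Exception hierarchy shared across the package."""


class GreySharpError(Exception):
    """Base class for all package-specific failures."""


class InvalidInputError(GreySharpError, ValueError):
    """An argument violates a documented precondition."""


class InvalidParameterError(GreySharpError, ValueError):
    """A tuning parameter is outside its admissible range."""


class DegenerateModelError(GreySharpError, ArithmeticError):
    """The GM(1,1) normal equations are singular for this sequence."""


class FormatError(GreySharpError, ValueError):
    """An image file could not be parsed as 8-bit grayscale."""


class FeatureUnavailableError(GreySharpError, RuntimeError):
    """An optional component (e.g. the Canny plugin) is not installed."""
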