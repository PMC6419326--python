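"""Exception hierarchy."""


class LeeacError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LeeacError, ValueError):
    """A hyperparameter is outside its valid range."""


class NoBimodalStructureError(LeeacError, ValueError):
    """Raised when global thresholding is attempted on a constant image."""


class PatchPlacementError(LeeacError, ValueError):
    """Raised when a sample patch cannot be placed inside its class region."""


class NumericalInstabilityError(LeeacError, ArithmeticError):
    """Raised when the level-set field becomes non-finite during evolution."""
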