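"""Exception hierarchy shared across the package."""


class IcmethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IcmethError, ValueError):
    """Invalid simulation or pipeline configuration."""


class AlignmentError(IcmethError, ValueError):
    """Sample/feature identifiers of two inputs do not line up."""


class RangeError(IcmethError, ValueError):
    """A value lies outside its declared bounds."""


class DegenerateDomainError(IcmethError, ValueError):
    """A column is constant (or otherwise degenerate) where variance is required."""


class ContractError(IcmethError, ValueError):
    """A documented precondition of an operation was violated."""


class NoCompleteCasesError(IcmethError, ValueError):
    """Complete-case filtering removed every participant."""


class ConvergenceError(IcmethError, RuntimeError):
    """An iterative fit failed to converge."""


class NonEstimableError(IcmethError, RuntimeError):
    """A model is not estimable (for example, complete separation in logistic fits)."""


class ParseError(IcmethError, ValueError):
    """A delimited-text input could not be parsed or failed validation."""
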