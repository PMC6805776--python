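"""Package exception types."""


class NkhifError(Exception):
    """Base class for package errors."""


class ModelDomainError(NkhifError, ValueError):
    """A state or argument lies outside the model's domain."""


class NumericError(NkhifError, ArithmeticError):
    """A model expression produced NaN or infinity."""


class InfeasibleEquilibriumError(NkhifError, RuntimeError):
    """No consistent untreated equilibrium inside the bounds."""


class StiffnessError(NkhifError, RuntimeError):
    """The ODE solver failed to converge on an interval."""


class IdentifiabilityError(NkhifError, RuntimeError):
    """The linearized estimation problem is rank-deficient."""
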