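"""Exception types shared across the package."""


class ASLDesignError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ASLDesignError, ValueError):
    """A physical or configuration parameter is out of its valid domain."""


class SingularInformationError(ASLDesignError, ArithmeticError):
    """The Fisher information matrix is (numerically) singular.

    For PCASL this typically signals a lack of arterial-transit-time
    information: when every sample time falls after the bolus has fully
    arrived, the CBF and ATT sensitivities become collinear.
    """


class InfeasibleDesignError(ASLDesignError):
    """A protocol cannot be evaluated: no averages fit in the scan-time
    budget, or no (slice, ATT) pair yields an invertible information matrix."""


class OptimizationFailedError(ASLDesignError):
    """The exchange search could not find any feasible candidate design."""


class UndefinedBiasError(ASLDesignError):
    """Single-PLD mismatch bias is undefined (model signal identically zero)."""
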