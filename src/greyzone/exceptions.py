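"""Exception hierarchy for the greyzone package."""


class GreyZoneError(Exception):
    """Base class for all package errors."""


class TableValidationError(GreyZoneError, ValueError):
    """Raised when an agreement-table input violates a structural precondition."""


class UndefinedCoefficientError(GreyZoneError, ZeroDivisionError):
    """Raised when a chance-corrected coefficient is undefined (P_e = 1)."""


class AgreementTooLowError(GreyZoneError, ValueError):
    """Raised when kappa <= 0, where grey-zone analysis is meaningless."""


class ThresholdDomainError(GreyZoneError, ValueError):
    """Raised when the threshold back-transform base is non-positive."""


class InfeasibleInjectionError(GreyZoneError, ValueError):
    """Raised when no feasible mass transfer achieves the target kappa."""
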