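"""Exception hierarchy shared across the package."""


class AkdScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(AkdScreenError, ValueError):
    """Invalid input data or parameters."""


class DomainError(AkdScreenError, ValueError):
    """Input outside the domain an operation is defined on (e.g. pediatric age)."""


class UsageError(AkdScreenError):
    """Operation called on an object it is not defined for."""


class CalibrationError(AkdScreenError):
    """Symptom-probability calibration could not meet its targets.

    Carries the best metrics achieved so the caller can inspect how far off
    the search ended.
    """

    def __init__(self, message: str, best: dict | None = None):
        super().__init__(message)
        self.best = best or {}
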