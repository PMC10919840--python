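"""Exception hierarchy for the analysis pipeline."""


class MyothermoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MyothermoError, ValueError):
    """Raised when inputs violate a documented precondition."""


class FitFailureError(MyothermoError, RuntimeError):
    """Raised when a regression does not converge or yields an
    inadmissible estimate (e.g. a non-positive Hill asymptote)."""


class AnalysisError(MyothermoError, RuntimeError):
    """Raised when a downstream analysis step has no solution on the
    data (no root, no sign change, no fixed point in range)."""
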