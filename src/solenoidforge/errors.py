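"""Exception hierarchy shared across the pipeline."""


class SolenoidForgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(SolenoidForgeError, ValueError):
    """A design specification field is out of its allowed range."""


class InfeasibleSpecError(SolenoidForgeError, ValueError):
    """No repeat count satisfies the length band and minimum-repeat rule."""


class InvalidParameterError(SolenoidForgeError, ValueError):
    """A numeric parameter (rate, threshold, schedule bound) is invalid."""


class InvalidInputError(SolenoidForgeError, ValueError):
    """Input data violates a shape or value contract."""


class InvalidStateError(SolenoidForgeError, RuntimeError):
    """An internal invariant was violated (e.g. empty population)."""


class OracleUnavailableError(SolenoidForgeError, RuntimeError):
    """A neural-oracle adapter was requested but its backend is absent.

    Raised explicitly rather than falling back silently: a run configured
    for a real predictor must never continue on a surrogate.
    """


class IncompleteReportError(SolenoidForgeError, ValueError):
    """A filter decision was requested before all required metrics exist."""
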