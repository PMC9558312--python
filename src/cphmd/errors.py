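"""Exception hierarchy for cphmd."""


class CphmdError(Exception):
    """Base class for all cphmd errors."""


class ConfigurationError(CphmdError):
    """Ill-formed system, constraint set, or run configuration."""


class ParameterError(CphmdError):
    """Invalid physical parameter (e.g. non-positive temperature)."""


class SingularityError(CphmdError):
    """Coincident point charges or another numerical singularity."""


class ContractViolationError(CphmdError):
    """A cached quantity was used after its inputs changed (stale state)."""


class IntegrationBlowupError(CphmdError):
    """Non-finite forces or coordinates encountered during time integration."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class UndefinedFractionError(CphmdError):
    """No frames could be classified as protonated or deprotonated."""


class NonIdentifiableError(CphmdError):
    """Titration data do not constrain the pKa (single plateau)."""


class PrecisionError(CphmdError):
    """A quadrature or fit did not converge to the requested precision."""
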