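"""Exception hierarchy.

Validation problems (bad shapes, bad values) raise :class:`ValidationError`;
missing upstream artifacts raise :class:`DependencyError`; numerical failures
of the kinetic fit raise :class:`FitError` subclasses. The CLI maps these to
distinct exit codes.
"""


class PetomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PetomicsError, ValueError):
    """Invalid configuration values (counts, rates, fractions out of range)."""


class ValidationError(PetomicsError, ValueError):
    """Invalid input data: bad shapes, ranges, or schema mismatches."""


class PairingError(ValidationError):
    """Tumor/normal samples cannot be matched one-to-one by patient."""


class InsufficientDataError(ValidationError):
    """Too few samples/pairs/frames for the requested analysis."""


class MissingGenesError(ValidationError):
    """Requested gene IDs absent from an expression matrix."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"genes absent from expression matrix: {self.missing}")


class DependencyError(PetomicsError):
    """A pipeline stage requires outputs of a stage that has not run."""


class FitError(PetomicsError):
    """Nonlinear fit failed."""


class DegenerateFitError(FitError, ValidationError):
    """The data admit no meaningful fit (e.g. an all-zero time-activity curve)."""


class FitConvergenceError(FitError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
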