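"""Exception hierarchy for evidence loading, reconstruction and simulation."""


class VoiHbpError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VoiHbpError):
    """An input table is missing, missing a column, or has an unknown tag."""


class ParseError(VoiHbpError):
    """A cell that must hold a number could not be parsed."""


class EvidenceValidationError(VoiHbpError):
    """An evidence base violates its documented invariants.

    Carries the individual diagnostics so callers can report them all.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(str(d) for d in self.diagnostics)
        super().__init__(f"evidence base failed validation: {lines}")


class InsufficientDataError(VoiHbpError):
    """A payload does not carry enough rows/points for its reconstruction."""


class ReconstructionError(VoiHbpError):
    """A distribution fit failed or the payload is unidentifiable.

    ``residual`` carries the best residual achieved, when one exists.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ImputationError(VoiHbpError):
    """Pooling or imputation was requested without an informed set."""


class ReconstructionWarning(UserWarning):
    """Non-fatal reconstruction issue (degenerate margin, poor fit, ...)."""
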