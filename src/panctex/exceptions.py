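"""Exception hierarchy for the texture-survival pipeline."""


class PanctexError(Exception):
    """Base class for all package errors."""


class FormatError(PanctexError):
    """Malformed or unreadable image/table input."""


class AlignmentError(PanctexError):
    """Mask and volume grids are not congruent."""


class EmptyROIError(PanctexError):
    """An ROI has no admissible voxels left for analysis."""


class DegenerateGLCMError(PanctexError):
    """No admissible in-mask pixel pair exists at the requested offset."""


class ExtractionError(PanctexError):
    """Feature extraction failed for a given subject/ROI.

    Carries enough identity to let a cohort pipeline drop the subject
    and log the reason instead of failing silently.
    """

    def __init__(self, message: str, subject: str | None = None, role: str | None = None):
        self.subject = subject
        self.role = role
        prefix = ""
        if subject is not None:
            prefix += f"subject={subject} "
        if role is not None:
            prefix += f"role={role} "
        super().__init__(prefix + message)


class NonIdentifiableError(PanctexError):
    """Model parameter cannot be identified (e.g. constant covariate)."""


class DivergenceError(PanctexError):
    """Likelihood maximization has no finite maximum (monotone likelihood)."""
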