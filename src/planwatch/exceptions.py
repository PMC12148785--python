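"""Exception hierarchy shared across the package."""


class PlanwatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlanwatchError):
    """Input file is not in the expected format / modality."""


class ValidationError(PlanwatchError):
    """Input parsed but violates an invariant (e.g. non-monotone DVH)."""


class UnsupportedOrientationError(FormatError):
    """Dose grid is not axial / identity-oriented."""


class UnitError(PlanwatchError):
    """A metric was requested in a unit the curve cannot supply."""


class AmbiguityError(PlanwatchError):
    """Automatic structure matching found an exact tie."""


class NoMatchError(PlanwatchError):
    """No protocol selection rule matched the plan."""


class VersioningError(PlanwatchError):
    """Library file header/schema is incompatible with this version."""
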