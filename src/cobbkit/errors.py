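"""Exception hierarchy for cobbkit.

All user-facing failures derive from :class:`CobbkitError` so callers (and the
CLI) can distinguish expected data problems from genuine bugs.
"""


class CobbkitError(Exception):
    """Base class for all cobbkit errors."""


class AnnotationValidationError(CobbkitError):
    """A keypoint annotation violates a structural invariant."""


class SchemaError(CobbkitError):
    """A file does not conform to the documented schema."""


class PairingError(CobbkitError):
    """Paired data could not be matched subject-by-subject."""


class DesignError(CobbkitError):
    """A crossed measurement design is incomplete."""


class GenerationError(CobbkitError):
    """Synthetic-spine parameters produce invalid geometry."""


class InsufficientDataError(CobbkitError):
    """Too few vertebrae/points for the requested fit."""


class ConditioningError(CobbkitError):
    """A least-squares design matrix is numerically degenerate."""
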