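"""Exception hierarchy for stagecal."""


class StageCalError(Exception):
    """Base class for all stagecal errors."""


class InvalidArgumentError(StageCalError, ValueError):
    """Non-finite or out-of-contract input."""


class ConfigurationError(StageCalError):
    """Inconsistent simulation or pipeline configuration."""


class NumericalError(StageCalError):
    """An iterative numerical procedure failed to converge."""


class ExtractionError(StageCalError):
    """Centerline extraction failed (no lines / insufficient contrast)."""


class DegenerateGeometryError(StageCalError):
    """Correspondence geometry does not constrain the solution."""


class IllConditionedGeometryError(DegenerateGeometryError):
    """Solution exists but is numerically unreliable."""


class RegistrationError(StageCalError):
    """Pairwise image registration failed."""


class AmbiguousOffsetError(RegistrationError):
    """Backends disagree by more than half a lattice period."""


class SchemaError(StageCalError):
    """Calibration file missing fields or has an unknown version."""
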