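"""Exception hierarchy shared across the simulator."""


class LedgerfedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LedgerfedError):
    """Invalid user-supplied configuration (sizes, probabilities, shapes)."""


class GenerationError(LedgerfedError):
    """Synthetic cohort generation failed (e.g. prevalence calibration)."""


class LookupError_(LedgerfedError):
    """Unknown identifier (patient, node, agreement, obligation)."""


class FormatError(LedgerfedError):
    """On-disk table violates the documented schema."""


class DataError(LedgerfedError):
    """In-memory data violates an invariant (e.g. negative timestamps)."""


class FitError(LedgerfedError):
    """Preprocessor statistics cannot be fitted."""


class SchemaError(LedgerfedError):
    """Episode/variable schema mismatch at transform or audit time."""


class SplitError(LedgerfedError):
    """Patient-level split cannot be formed."""


class TrainingError(LedgerfedError):
    """Model training precondition violated."""


class ShapeError(LedgerfedError):
    """Tensor shape mismatch."""


class IdentityError(LedgerfedError):
    """Unregistered node or bad signature."""


class DegenerateStakeError(LedgerfedError):
    """All stakes are zero; Eq.-style proportional sampling undefined."""


class SamplingError(LedgerfedError):
    """Committee sampling precondition violated."""


class ScoringError(LedgerfedError):
    """Contribution scoring undefined (e.g. single-class validation set)."""


class RegistrationError(LedgerfedError):
    """Agreement registration violates an invariant."""


class StateError(LedgerfedError):
    """Contract lifecycle violation (settle twice, post after settle, ...)."""


class MetricError(LedgerfedError):
    """Evaluation metric undefined on the given inputs."""


class AggregationError(LedgerfedError):
    """Seed-replicate aggregation precondition violated."""
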