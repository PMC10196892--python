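"""Exception hierarchy for the medgesture pipeline."""


class MedGestureError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MedGestureError):
    """A required column or label is missing or unrecognised."""


class MalformedInputError(MedGestureError):
    """A row of an input file could not be parsed."""


class ConfigurationError(MedGestureError):
    """An operation was given inconsistent parameters."""


class EmptyInputError(MedGestureError):
    """An operation requires at least one record and got none."""


class BalancingError(MedGestureError):
    """Class balancing is impossible (an activity has no valid gestures)."""


class TrainingError(MedGestureError):
    """Optimisation diverged (non-finite loss)."""


class UndefinedMetricError(MedGestureError):
    """A ratio metric has a zero denominator for every requested value."""
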