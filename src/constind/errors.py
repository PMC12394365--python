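"""Exception hierarchy for the constind pipeline.

Every stage raises a subclass of :class:`ConstindError`, so callers can
catch pipeline failures without masking programming errors.
"""


class ConstindError(Exception):
    """Base class for all constind errors."""


class ConfigurationError(ConstindError):
    """Invalid generator or run configuration."""


class TableFormatError(ConstindError):
    """Malformed experiment or means table (names the offending row/column)."""


class EstimationError(ConstindError):
    """Family-means estimation cannot proceed (empty cell, too few families...)."""


class InferenceError(ConstindError):
    """Trade-off inference cannot proceed (degenerate null, constant input...)."""


class PipelineError(ConstindError):
    """End-to-end run failure, carrying the stage and (trait, phosphorus) context."""
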