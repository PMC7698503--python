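"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PPGAffectError`, so callers can
catch pipeline failures without masking programming errors.
"""


class PPGAffectError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PPGAffectError):
    """A required configuration value is missing or invalid."""


class ParseError(PPGAffectError):
    """A data file could not be parsed."""


class ValidationError(PPGAffectError):
    """Input data violates a documented invariant."""


class SegmentationError(PPGAffectError):
    """A stimulus window does not fit inside the recording."""


class SchemaError(PPGAffectError):
    """A feature-matrix file does not match the expected column schema."""


class BeatDetectionError(PPGAffectError):
    """Too few pulse peaks were found in a segment."""


class InsufficientBeatsError(PPGAffectError):
    """A feature needs more beat intervals than the segment provides."""


class StructuralError(PPGAffectError):
    """Peaks and valleys do not alternate as a pulse waveform requires."""


class OutlierFilterError(PPGAffectError):
    """Robust outlier filtering removed every row."""


class StageError(PPGAffectError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
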