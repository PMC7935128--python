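"""Exception hierarchy for the gait pipeline.

Every error raised by the package derives from :class:`GaitError` so callers
can catch pipeline failures without masking programming errors.  Validation
errors always name the offending column, frame, or marker.
"""

from __future__ import annotations


class GaitError(Exception):
    """Base class for all mousegait errors."""


class FormatError(GaitError):
    """A trial file or config violates the on-disk dialect."""


class EmptyInputError(FormatError):
    """A trial file contains no data rows."""


class ConfigError(GaitError):
    """An invalid configuration value or unknown preset name."""


class GeometryError(GaitError):
    """Degenerate marker geometry (e.g. a zero-length segment)."""


class ReachabilityError(GaitError):
    """A requested limb pose exceeds the two-segment reach."""


class MissingDataError(GaitError):
    """A required sample is missing (NaN) where a value is needed."""


class SegmentationError(GaitError):
    """Gait-cycle segmentation failed."""


class NoContactError(SegmentationError):
    """No stance run was found in the paw trajectory."""


class NoSwingError(SegmentationError):
    """The paw never leaves stance (constant / all-contact trace)."""


class InsufficientCyclesError(SegmentationError):
    """Fewer gait cycles than the operation requires."""


class MalformedEventError(SegmentationError):
    """Footstrike/toe-off events do not alternate as required."""


class InsufficientSampleError(GaitError):
    """A statistical test needs at least two values per group."""


class DegenerateVarianceError(GaitError):
    """Zero pooled variance with unequal group means: t is undefined."""


class PipelineStageError(GaitError):
    """A multi-stage analysis failed; carries the stage name.

    Parameters
    ----------
    stage : str
        Name of the pipeline stage ("kinematics", "events", "parameters").
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
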