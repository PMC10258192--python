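"""Exception hierarchy for crowdscope.

Every operational failure raises a subclass of :class:`CrowdscopeError`
so callers (and the pipeline runner) can distinguish analysis failures
from programming errors.
"""


class CrowdscopeError(Exception):
    """Base class for all crowdscope errors."""


class InvalidGeometryError(CrowdscopeError):
    """Scene geometry is degenerate (e.g. zero-area cell)."""


class PlacementError(CrowdscopeError):
    """Condensates could not be placed without overlap within the retry budget."""


class EmptyRatioError(CrowdscopeError):
    """No pixel survived the validity criteria of the ratio computation."""


class NormalizationError(CrowdscopeError):
    """Control group empty or with non-positive mean."""


class DegenerateSegmentationError(CrowdscopeError):
    """Image has no intensity contrast within the mask; phases undefined."""


class InsufficientPixelsError(CrowdscopeError):
    """A phase region has fewer valid pixels than the configured floor."""


class InsufficientDataError(CrowdscopeError):
    """Too few samples, cells or fits for the requested statistic."""


class FitFailureError(CrowdscopeError):
    """Nonlinear fit failed to converge after multistart."""


class PipelineStageError(CrowdscopeError):
    """A pipeline stage failed; carries the stage name and cell id."""

    def __init__(self, stage: str, cell_id, cause: Exception):
        self.stage = stage
        self.cell_id = cell_id
        self.cause = cause
        super().__init__(f"stage {stage!r} failed for cell {cell_id!r}: {cause}")
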