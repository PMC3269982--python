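"""Exception hierarchy for the measurement pipeline."""


class CortiscanError(Exception):
    """Base class for all package errors."""


class RoiBoundsError(CortiscanError):
    """ROI box extends past an image edge."""


class DegenerateHistogramError(CortiscanError):
    """Thresholding requested on an image with a single intensity level."""


class ShapeMismatchError(CortiscanError):
    """Two grids that must share a shape do not."""


class ParameterError(CortiscanError):
    """An argument is outside its admissible range."""


class NoObjectError(CortiscanError):
    """A binary mask that must contain foreground is empty."""


class DiscontinuousObjectError(CortiscanError):
    """No 8-connected left-to-right medial path spans the object."""


class InsufficientSupportError(CortiscanError):
    """Too few margin columns to fit the requested polynomial."""


class MeasurementError(CortiscanError):
    """Too many width measurements failed to intersect the lower margin."""


class DegenerateTrainingError(CortiscanError):
    """SVM training requires both classes to be present."""


class SolverError(CortiscanError):
    """The quadratic-programming solver did not converge."""


class PipelineStageError(CortiscanError):
    """Wraps a stage failure with the stage name and mandible side."""

    def __init__(self, stage: str, side: str, cause: Exception):
        self.stage = stage
        self.side = side
        self.cause = cause
        super().__init__(f"stage '{stage}' failed on side '{side}': {cause}")
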