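"""Exception and warning hierarchy for the Relaxation Index pipeline."""


class RelaxIndexError(Exception):
    """Base class for all pipeline errors."""


class ImageShapeError(RelaxIndexError):
    """Raised when an image violates a size/shape precondition."""


class BoundaryNotFoundError(RelaxIndexError):
    """No panel seam exceeds the gradient floor in a composite export."""


class ParameterError(RelaxIndexError):
    """A stage parameter is out of its valid range."""


class NormalizationError(RelaxIndexError):
    """Min-max normalization of a constant signal was requested."""


class EmptyRoiError(RelaxIndexError):
    """No row of the envelope exceeds the ROI threshold."""


class LayerFitError(RelaxIndexError):
    """A layer trace could not be fitted from the surviving candidates."""

    def __init__(self, layer: str, message: str):
        self.layer = layer
        super().__init__(f"layer fit failed ({layer}): {message}")


class SegmentationStageError(RelaxIndexError):
    """Wraps a failure inside segment_bscan with the offending stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"segmentation stage '{stage}' failed: {cause}")


class ScanLineNotFoundError(RelaxIndexError):
    """No horizontal green run long enough to be the scan-position arrow."""


class MarkerValidationError(RelaxIndexError):
    """One or more marker rows failed validation; offending rows listed."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("marker validation failed:\n" + "\n".join(self.problems))


class ProjectionError(RelaxIndexError):
    """A marker projects outside the segmented trace span."""


class PairingError(RelaxIndexError):
    """Displacement requested between projections of different markers/eyes."""


class ModelSpecError(RelaxIndexError):
    """The analysis table violates the mixed-model design requirements."""


class PhantomSpecError(RelaxIndexError):
    """A phantom specification is internally inconsistent."""


class ShortMarkerCountWarning(UserWarning):
    """Fewer/more than the nominal ten vessel crossings contributed to an RI."""


class RejectionSkippedWarning(UserWarning):
    """Outlier rejection skipped because a layer has too few candidates."""
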