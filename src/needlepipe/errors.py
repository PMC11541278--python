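"""Exception hierarchy shared by all pipeline stages."""


class NeedlePipeError(Exception):
    """Base class for all errors raised by needlepipe."""


class GeometryError(NeedlePipeError):
    """Invalid image geometry (spacing, orientation, out-of-grid needle...)."""


class FormatError(NeedlePipeError):
    """Malformed volume file; the message names the offending field."""


class SegmentationEmptyError(NeedlePipeError):
    """A segmentation stage produced (or received) an empty mask."""


class DegenerateMaskError(NeedlePipeError):
    """Mask too small or degenerate for axis estimation."""


class AxisAmbiguousError(NeedlePipeError):
    """Principal-axis direction undefined (tied leading eigenvalues)."""


class CorridorEmptyError(NeedlePipeError):
    """No mask pixels fall inside the axis corridor: segmentation and
    fitted axis disagree."""


class PlacementError(NeedlePipeError):
    """Could not place a distractor disjoint from the needle after
    bounded retries."""


class CapabilityError(NeedlePipeError):
    """An optional runtime (e.g. a neural framework) is not available."""


class StageError(NeedlePipeError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
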