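"""Exception hierarchy for the bead-quantification pipeline."""


class IBRPError(Exception):
    """Base class for all pipeline errors."""


class ImageReadError(IBRPError):
    """The file could not be read as an image."""


class NotGrayscaleError(ImageReadError):
    """The image is not single-channel grayscale."""


class InvalidExposureError(IBRPError):
    """Exposure time is missing or non-positive."""


class ShapeMismatchError(IBRPError):
    """Image and label map shapes differ."""


class EmptyTableError(IBRPError):
    """A table operation received no rows."""


class ThresholdError(IBRPError):
    """Automatic thresholding found no bimodal separation."""


class PlacementError(IBRPError):
    """Requested beads cannot be placed in the field.

    Carries ``achievable`` — how many beads were successfully placed.
    """

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"could not place {requested} beads; achievable count is {achievable}"
        )


class DegenerateSampleError(IBRPError):
    """A statistical test received a sample it cannot handle."""


class NormalizationError(IBRPError):
    """A normalizer (prey input, bait input, exposure) is zero or negative."""
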