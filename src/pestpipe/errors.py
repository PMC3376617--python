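"""Exception hierarchy for the pipeline.

Each stage raises a distinct error type so callers (and the CLI exit
codes) can tell segmentation failures from model or framing problems.
"""


class PestPipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidImageError(PestPipeError):
    """The input raster is empty or not an H x W x 3 8-bit image."""


class SegmentationError(PestPipeError):
    """No foreground region survived thresholding/denoising."""


class FeatureError(PestPipeError):
    """Feature extraction on an empty or degenerate region."""


class ModelError(PestPipeError):
    """Model file missing, corrupt, or incompatible with the input."""


class TrainingError(PestPipeError):
    """Training preconditions violated (single class, NaNs, ...)."""


class FramingError(PestPipeError):
    """A frame fails structural validation (head/end byte, length, seq gap)."""


class DeliveryError(PestPipeError):
    """The link simulator exhausted its retry budget.

    Carries the transmission log accumulated up to the failure in
    ``log`` so callers can inspect what happened.
    """

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log
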