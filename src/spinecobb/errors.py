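"""Exception taxonomy for the measurement pipeline.

Every error a caller can act on gets its own class; the CLI maps the whole
hierarchy to exit code 1 and argparse/usage problems to exit code 2.
"""


class SpineCobbError(Exception):
    """Base class for all package errors."""


class InputError(SpineCobbError):
    """A file could not be read or is not what it claims to be."""


class UnsupportedFormatError(InputError):
    """Readable file, but a payload the pipeline does not handle (color,
    multi-frame, palette...). The message names the offending condition."""


class AmbiguousMaskError(InputError):
    """A mask raster with more than two distinct pixel values; probabilistic
    masks are rejected rather than silently thresholded."""


class EmptyMaskError(InputError):
    """A mask with no foreground pixels."""


class PreconditionError(SpineCobbError, ValueError):
    """A documented precondition of an operation was violated."""


class ParameterError(PreconditionError):
    """A configuration parameter is outside its documented range."""


class DomainError(PreconditionError):
    """Curve evaluation requested outside the fitted domain."""


class TooShortSpineError(SpineCobbError):
    """Fewer foreground rows than a degree-10 fit can support."""


class FitFailureError(SpineCobbError):
    """Rank-deficient / ill-conditioned polynomial fit."""


class MaskValidationError(SpineCobbError):
    """Mask failed a structural check (e.g. fragmented into several blobs)."""


class NoDetectionError(SpineCobbError):
    """The segmentation backend produced no candidate instances."""


class BackendFailureError(SpineCobbError):
    """The pluggable segmentation backend raised; carries its message."""


class UndefinedMetricError(SpineCobbError):
    """An agreement statistic is undefined on this input (zero variance,
    chance agreement probability of one, ...)."""


class PhantomSpecError(SpineCobbError):
    """A synthetic phantom specification that cannot be rasterized
    (band leaves the frame, half-width too small, ...)."""


class StageError(SpineCobbError):
    """Wraps an error raised inside the composed pipeline, recording which
    stage failed so reports and logs can name it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"{stage}: {cause}")
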