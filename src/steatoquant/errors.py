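"""Exception hierarchy shared across the package."""


class SteatoQuantError(Exception):
    """Base class for all domain errors raised by steatoquant."""


class FormatError(SteatoQuantError):
    """An input file is not a readable raster image of a supported format."""


class DegenerateInputError(SteatoQuantError):
    """An image or data vector has no exploitable structure.

    Examples: a constant-intensity slide (no tissue/vacuole contrast),
    an all-white slide (no tissue), or a zero-variance sample handed to a
    correlation or normality test.
    """


class InsufficientDataError(SteatoQuantError):
    """Fewer observations than the statistical procedure requires."""


class InvalidSampleError(SteatoQuantError):
    """An assay sample violates its physical preconditions.

    Negative blank-corrected absorbance, or missing/non-positive protein
    content where per-mg normalisation was requested.
    """


class FeasibilityError(SteatoQuantError):
    """A synthetic-slide target fat fraction could not be reached.

    Raised when vacuole placement hits its attempt cap with a shortfall
    larger than the documented tolerance; carries the achieved fraction.
    """

    def __init__(self, message: str, achieved_fraction: float | None = None):
        super().__init__(message)
        self.achieved_fraction = achieved_fraction
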