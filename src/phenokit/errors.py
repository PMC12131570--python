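"""Exception hierarchy for phenokit.

Every recoverable analysis failure raises a subclass of :class:`PhenoKitError`
so pipelines can catch one base class and degrade gracefully (e.g. report
pixel units when no reference object is found).
"""


class PhenoKitError(Exception):
    """Base class for all phenokit errors."""


class InvalidParameterError(PhenoKitError, ValueError):
    """A parameter violates its documented precondition."""


class CoinNotFoundError(PhenoKitError):
    """No contour qualified as a circular reference coin."""


class MarkerNotFoundError(PhenoKitError):
    """No quadrilateral field marker passed detection/verification."""


class UncalibratedError(PhenoKitError):
    """A physical-unit value was requested without a scale calibration."""


class DegenerateGeometryError(PhenoKitError):
    """Geometric input is degenerate (coincident points, collinear corners)."""


class InsufficientDataError(PhenoKitError):
    """Too few samples/keypoints for the requested model."""


class EmptyMaskError(PhenoKitError):
    """An operation requiring foreground pixels received an empty mask."""


class OutOfDomainError(PhenoKitError):
    """A curve was evaluated beyond its fitted domain plus tolerance."""
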