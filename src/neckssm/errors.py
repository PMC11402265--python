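"""Exception hierarchy shared across the pipeline stages."""


class NeckSSMError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NeckSSMError, ValueError):
    """A geometric or statistical parameter is outside its valid domain."""


class GeometryError(NeckSSMError):
    """A geometric operation failed (self-folding tube, open mesh, ...)."""


class NoDistalEndError(NeckSSMError):
    """The 10% diameter-increase rule is never satisfied on the centerline."""


class DegenerateSegmentError(NeckSSMError):
    """The neck segment is too short to place the requested levels."""


class OpenContourError(GeometryError):
    """A cutting plane did not intersect the mesh in a closed polyline."""


class InsufficientCenterlineError(NeckSSMError):
    """The centerline does not extend far enough for a direction fit."""

    def __init__(self, message: str, available_mm: float | None = None):
        super().__init__(message)
        self.available_mm = available_mm
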