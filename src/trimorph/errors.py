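"""Exception hierarchy shared by all trimorph modules."""


class TrimorphError(Exception):
    """Base class for all trimorph errors."""


class InvalidParameterError(TrimorphError, ValueError):
    """A parameter violates its documented precondition."""


class BoundsError(TrimorphError, ValueError):
    """Geometry does not fit inside the requested voxel volume."""


class DegenerateGeometryError(TrimorphError, ValueError):
    """Input points are collinear/coincident where a surface or plane is needed."""


class NonStarShapedError(TrimorphError, ValueError):
    """The projected annulus is not star-shaped about its centroid."""


class IncompleteAnnotationError(TrimorphError, ValueError):
    """An annotation file does not cover all required angular stations."""

    def __init__(self, missing_angles_deg):
        self.missing_angles_deg = sorted(float(a) for a in missing_angles_deg)
        super().__init__(
            "annotation is missing angular stations (deg): "
            + ", ".join(f"{a:g}" for a in self.missing_angles_deg)
        )


class DegenerateDataError(TrimorphError, ValueError):
    """Statistical input with no usable variance (e.g. constant differences)."""
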