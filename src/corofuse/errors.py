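"""Exception hierarchy for the fusion pipeline.

Every stage raises a subclass of :class:`CorofuseError` so the pipeline driver
can attach stage provenance without catching bare exceptions.
"""


class CorofuseError(Exception):
    """Base class for all package errors."""


class InvalidContourError(CorofuseError):
    """Contour does not satisfy the Contour2D/Contour3D invariants."""


class InvalidCenterlineError(CorofuseError):
    """Centerline degenerate (too few distinct points)."""


class ParameterError(CorofuseError):
    """A parameter violates its documented precondition."""


class EmptyAnnotationError(CorofuseError):
    """No pixels matched the annotation colour on a frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"no annotation pixels found in frame {frame_index}")


class DegenerateMaskError(CorofuseError):
    """Binary mask has fewer than 3 non-collinear foreground pixels."""


class SeriesError(CorofuseError):
    """Pullback series unusable (fewer than 2 frames survive processing)."""


class ZeroOverlapError(CorofuseError):
    """Consecutive contours share no area at any candidate rotation."""


class LandmarkMismatchError(CorofuseError):
    """Carina midpoint lies too far from the centerline."""


class CoverageError(CorofuseError):
    """OCT stack cannot be hosted on the centerline."""


class EmptyCloudError(CorofuseError):
    """Region selection removed every point."""


class ReconstructionError(CorofuseError):
    """Surface reconstruction produced no usable mesh."""


class CollapseError(CorofuseError):
    """Inward polygon offset collapsed the contour."""


class EmptySectionError(CorofuseError):
    """A cutting plane does not intersect the mesh."""


class EmbeddingError(CorofuseError):
    """Calcification embedding (mesh union) failed."""

    def __init__(self, mesh_id, message: str | None = None):
        self.mesh_id = mesh_id
        super().__init__(message or f"embedding failed for calcification {mesh_id}")


class NoReferenceError(CorofuseError):
    """MLA sits at the proximal boundary; no reference segment exists."""


class ProfileError(CorofuseError):
    """Too few valid cross-sections to build an area profile."""


class DegenerateComparisonError(CorofuseError):
    """All vertex distances fell below the exclusion threshold."""


class ConfigError(CorofuseError):
    """Pipeline configuration invalid (unknown key or bad threshold)."""


class RenderError(CorofuseError):
    """Rendered section exceeds the imaging field of view."""


class SpecError(CorofuseError):
    """Phantom specification internally inconsistent."""
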