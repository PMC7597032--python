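"""Exception hierarchy shared across the pipeline stages."""


class PedarchError(Exception):
    """Base class for all package-specific errors."""


class MeshParseError(PedarchError):
    """An STL file could not be read or describes no geometry."""


class MeshValidationError(PedarchError):
    """A mesh violates a structural invariant (too few vertices, bad faces)."""


class PlaneFitError(PedarchError):
    """Ground-plane fitting failed (collinear or degenerate vertices)."""


class GeometryError(PedarchError):
    """A geometric construction is degenerate (e.g. zero-length axis)."""


class MaskingError(PedarchError):
    """Footprint masking failed (empty footprint, degenerate hull)."""


class InsufficientDataError(PedarchError):
    """Not enough observations for the requested statistic."""


class DegeneracyWarning(UserWarning):
    """A bone has no dominant long axis; PCA ordering is unstable."""
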