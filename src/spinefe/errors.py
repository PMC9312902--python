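"""Exception hierarchy for the spinefe pipeline.

Every pipeline stage raises a subclass of :class:`SpineFEError` so callers can
distinguish modelling problems from programming errors.
"""


class SpineFEError(Exception):
    """Base class for all spinefe errors."""


class ValidationError(SpineFEError, ValueError):
    """A parameter fell outside its documented range; names the field."""


class GeometryError(SpineFEError):
    """Invalid or degenerate spine geometry (e.g. zero-length ligament)."""


class CTSynthesisError(SpineFEError):
    """Synthetic CT rasterization could not represent the requested geometry."""


class CalibrationError(SpineFEError):
    """Phantom calibration failed (missing insert, HUb == HUw, ...)."""


class DensitometryError(SpineFEError):
    """ROI placement or BMD computation failed."""


class MaterialError(SpineFEError):
    """Material mapping failed (non-positive density, element outside volume)."""


class MeshError(SpineFEError):
    """Mesh generation or validation failed (inverted elements, ...)."""


class FESingularError(SpineFEError):
    """The constrained stiffness matrix is singular (free rigid-body mode)."""


class FENonConvergenceError(SpineFEError):
    """Tension-only or damage iteration failed to converge."""


class PipelineError(SpineFEError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
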