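"""Exception hierarchy for fishstereo.

Every hard failure raised by the library derives from :class:`FishStereoError`
so callers (and the CLI) can catch one base class.
"""


class FishStereoError(Exception):
    """Base class for all fishstereo errors."""


class PointBehindCameraError(FishStereoError):
    """A point with z <= 0 in the camera frame cannot be projected."""


class UndistortionError(FishStereoError):
    """Fixed-point lens undistortion failed to converge within the cap."""


class TotalInternalReflectionError(FishStereoError):
    """The Snell arcsin argument exceeds 1: no transmitted ray exists."""


class RefractionDomainError(FishStereoError):
    """No incidence angle in the valid bracket solves the refraction map."""


class PortGeometryError(FishStereoError):
    """Flat-port geometry is inconsistent (e.g. d <= T / cos(beta))."""


class DegenerateGeometryError(FishStereoError):
    """Stereo rays (near-)parallel or otherwise unusable for triangulation."""


class DegenerateConfigurationError(FishStereoError):
    """Calibration input is degenerate (collinear points, identical poses)."""


class InsufficientViewsError(FishStereoError):
    """Fewer target views than Zhang's method needs (at least 3)."""


class NonPositiveDefiniteConicError(FishStereoError):
    """The estimated image of the absolute conic is not positive definite."""


class MissingKeypointError(FishStereoError):
    """A keypoint required for measurement is not visible in both views."""


class SchemaError(FishStereoError):
    """An annotation file violates the COCO-dialect schema."""
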