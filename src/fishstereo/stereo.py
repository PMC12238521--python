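"""Stereo triangulation and fish body-length measurement.

Two calibrated views with projection matrices M1, M2 constrain a world point
(X, Y, Z) through the homogeneous projections; eliminating the projective
depths gives two linear equations per view,

``(u m31 - m11) X + (u m32 - m12) Y + (u m33 - m13) Z = m14 - u m34``
``(v m31 - m21) X + (v m32 - m22) Y + (v m33 - m23) Z = m24 - v m34``,

and the 4x3 stacked system is solved in the least-squares sense (orthogonal
factorisation via ``numpy.linalg.lstsq``; no normal equations).

Body length is the Euclidean distance between the triangulated mouth point
and a tail point (by default the midpoint of the two tail-fin landmarks).
Accuracy statistics follow the standard definitions: per-fish relative error
``RE = |L_t - L_a| / L_a * 100%`` and the mean relative percentage error
MRPE over fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    ProjectionMatrix,
    metric_to_pixel,
    pixel_to_metric,
    project_homogeneous,
    projection_matrix,
)
from .errors import DegenerateGeometryError, MissingKeypointError
from .keypoints import KEYPOINT_NAMES, FishKeypoints
from .refraction import FlatPort, RefractionModel, correct_keypoints

__all__ = [
    "RigCamera",
    "StereoRig",
    "FishMeasurement",
    "ErrorStats",
    "TAIL_RULES",
    "triangulate",
    "fish_length",
    "measure_fish",
    "relative_error",
    "mrpe",
]

TAIL_RULES = ("midpoint", "tail_fin1", "tail_fin2")


@dataclass(frozen=True)
class RigCamera:
    """One camera of a stereo rig: intrinsics, pose and its flat port."""

    intrinsics: CameraIntrinsics
    extrinsics: CameraExtrinsics
    port: FlatPort

    @property
    def projection(self) -> ProjectionMatrix:
        return projection_matrix(self.intrinsics, self.extrinsics)


@dataclass(frozen=True)
class StereoRig:
    """A calibrated binocular rig sharing one world frame (by convention the
    left-camera frame)."""

    left: RigCamera
    right: RigCamera
    image_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        baseline = np.linalg.norm(
            self.left.extrinsics.camera_center - self.right.extrinsics.camera_center
        )
        if baseline <= 0:
            raise ValueError("stereo rig needs distinct camera centers")
        for cam in (self.left, self.right):
            if np.linalg.matrix_rank(cam.projection.m) != 3:
                raise ValueError("projection matrix must have rank 3")

    @property
    def baseline_mm(self) -> float:
        return float(
            np.linalg.norm(
                self.left.extrinsics.camera_center
                - self.right.extrinsics.camera_center
            )
        )


@dataclass
class FishMeasurement:
    """Result of measuring one fish: per-keypoint 3D coordinates (mm, world
    frame), the body length and per-keypoint reprojection residuals."""

    points3d: dict[str, np.ndarray]
    length_mm: float
    head_point: np.ndarray
    tail_point: np.ndarray
    residuals_px: dict[str, float] = field(default_factory=dict)


@dataclass
class ErrorStats:
    """Per-fish relative errors (%) and their mean (MRPE, %)."""

    re_list: list[float]
    mrpe: float

    @classmethod
    def from_lengths(cls, measured, actual) -> "ErrorStats":
        res = [relative_error(lt, la) for lt, la in zip(measured, actual, strict=True)]
        return cls(re_list=res, mrpe=mrpe(list(zip(measured, actual))))


def _triangulation_rows(pixel: np.ndarray, m: np.ndarray):
    u, v = float(pixel[0]), float(pixel[1])
    a = np.array(
        [
            [u * m[2, 0] - m[0, 0], u * m[2, 1] - m[0, 1], u * m[2, 2] - m[0, 2]],
            [v * m[2, 0] - m[1, 0], v * m[2, 1] - m[1, 1], v * m[2, 2] - m[1, 2]],
        ]
    )
    b = np.array([m[0, 3] - u * m[2, 3], m[1, 3] - v * m[2, 3]])
    return a, b


def triangulate(
    p_left: np.ndarray,
    p_right: np.ndarray,
    m1: ProjectionMatrix,
    m2: ProjectionMatrix,
) -> np.ndarray:
    """Least-squares triangulation of one pixel correspondence.

    Builds the 4x3 linear system from both views and solves it by
    orthogonal-factorisation least squares.  Raises
    :class:`DegenerateGeometryError` when the two back-projected rays are
    parallel within 1e-8 rad (e.g. identical projection matrices).
    """
    d1 = m1.ray_direction(p_left)
    d2 = m2.ray_direction(p_right)
    sin_angle = np.linalg.norm(np.cross(d1, d2))
    if sin_angle <= 1e-8:
        raise DegenerateGeometryError(
            "back-projected rays are (near-)parallel; cannot triangulate"
        )
    a1, b1 = _triangulation_rows(p_left, m1.m)
    a2, b2 = _triangulation_rows(p_right, m2.m)
    a = np.vstack([a1, a2])
    b = np.concatenate([b1, b2])
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    return x


def fish_length(head: np.ndarray, tail: np.ndarray) -> float:
    """Euclidean distance (mm) between the mouth and tail 3D points."""
    return float(np.linalg.norm(np.asarray(head, float) - np.asarray(tail, float)))


def relative_error(l_t: float, l_a: float) -> float:
    """RE = |L_t - L_a| / L_a * 100 (%)."""
    if not l_a > 0:
        raise ValueError("reference length must be > 0")
    return abs(l_t - l_a) / l_a * 100.0


def mrpe(pairs: list[tuple[float, float]]) -> float:
    """Mean relative percentage error over (measured, actual) pairs."""
    if len(pairs) == 0:
        raise ValueError("MRPE needs at least one length pair")
    return float(np.mean([relative_error(lt, la) for lt, la in pairs]))


def _ideal_pixels(kps: FishKeypoints, k: CameraIntrinsics) -> np.ndarray:
    """Undistorted (ideal pinhole) pixels for linear triangulation."""
    if not k.has_distortion:
        return kps.xy
    k0 = CameraIntrinsics(
        focal_length_mm=k.focal_length_mm,
        dx_mm=k.dx_mm,
        dy_mm=k.dy_mm,
        skew=k.skew,
        principal_point=k.principal_point,
    )
    return np.array([metric_to_pixel(pixel_to_metric(p, k), k0) for p in kps.xy])


def _tail_3d(points3d: dict[str, np.ndarray], tail_rule: str) -> np.ndarray:
    if tail_rule not in TAIL_RULES:
        raise ValueError(f"tail_rule must be one of {TAIL_RULES}")
    if tail_rule == "midpoint":
        fins = [points3d[n] for n in ("tail_fin1", "tail_fin2") if n in points3d]
        if not fins:
            raise MissingKeypointError(
                "no tail-fin keypoint visible in both views"
            )
        return np.mean(fins, axis=0)
    if tail_rule not in points3d:
        raise MissingKeypointError(
            f"required keypoint '{tail_rule}' not visible in both views"
        )
    return points3d[tail_rule]


def measure_fish(
    kps_left: FishKeypoints,
    kps_right: FishKeypoints,
    rig: StereoRig,
    model: RefractionModel | None = RefractionModel.PARALLEL,
    tail_rule: str = "midpoint",
) -> FishMeasurement:
    """Full single-fish measurement: correct, triangulate, measure.

    Both views are refraction-corrected with *model* (``None`` skips the
    correction, i.e. treats the underwater pixels as if taken in air), every
    keypoint visible in both views is triangulated, and the body length is
    the distance between the mouth point and the tail point selected by
    *tail_rule* ("midpoint" of the two tail fins — degrading to the one
    visible fin — or a specific fin).

    Raises :class:`MissingKeypointError` when the mouth or every tail-fin
    keypoint is missing from either view.
    """
    if model is not None:
        kps_left = correct_keypoints(
            kps_left, rig.left.intrinsics, rig.left.port, model
        )
        kps_right = correct_keypoints(
            kps_right, rig.right.intrinsics, rig.right.port, model
        )
    m1, m2 = rig.left.projection, rig.right.projection
    px_left = _ideal_pixels(kps_left, rig.left.intrinsics)
    px_right = _ideal_pixels(kps_right, rig.right.intrinsics)
    points3d: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    for i, name in enumerate(KEYPOINT_NAMES):
        if not (kps_left.visibility[i] and kps_right.visibility[i]):
            continue
        try:
            p = triangulate(px_left[i], px_right[i], m1, m2)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"keypoint '{name}': {exc}") from exc
        points3d[name] = p
        r1 = np.linalg.norm(project_homogeneous(m1, p) - px_left[i])
        r2 = np.linalg.norm(project_homogeneous(m2, p) - px_right[i])
        residuals[name] = float(np.sqrt((r1**2 + r2**2) / 2.0))
    if "mouth" not in points3d:
        raise MissingKeypointError("mouth keypoint not visible in both views")
    head = points3d["mouth"]
    tail = _tail_3d(points3d, tail_rule)
    return FishMeasurement(
        points3d=points3d,
        length_mm=fish_length(head, tail),
        head_point=head,
        tail_point=tail,
        residuals_px=residuals,
    )
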