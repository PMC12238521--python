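"""Pinhole camera model and coordinate-system mappings.

Four coordinate frames are used throughout the package:

* **world** — (X_w, Y_w, Z_w) in mm, an arbitrary fixed frame (by default the
  left-camera frame of a stereo rig);
* **camera** — (X_c, Y_c, Z_c) in mm, origin at the optical centre, z along
  the optical axis (projectable points have z > 0);
* **metric image** — (x, y) in mm on the image plane at focal distance f;
* **pixel** — (u, v) in px, 0-based, x right, y down, origin at the top-left
  corner; the principal point (u0, v0) lives in the same frame.

Points are plain numpy arrays (shape ``(2,)``/``(3,)`` or ``(N, 2)``/
``(N, 3)``); the functions below document which frame each argument is in.

Lens distortion is the standard 2-term radial model applied in metric image
coordinates: ``x_d = x * (1 + k1 r^2 + k2 r^4)`` with ``r^2 = x^2 + y^2`` in
mm^2, so k1 has units mm^-2 and k2 mm^-4.  Both default to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PointBehindCameraError, UndistortionError

__all__ = [
    "CameraIntrinsics",
    "CameraExtrinsics",
    "ProjectionMatrix",
    "world_to_camera",
    "camera_to_pixel",
    "metric_to_pixel",
    "pixel_to_metric",
    "projection_matrix",
    "project_homogeneous",
]

_UNDISTORT_MAX_ITER = 20
_UNDISTORT_TOL_MM = 1e-12


@dataclass(frozen=True)
class CameraIntrinsics:
    """Internal camera parameters.

    Parameters
    ----------
    focal_length_mm
        Focal length f (mm), > 0.
    dx_mm, dy_mm
        Physical pixel pitch (mm/px) along u and v; the pixel scales are
        ``1/dx`` and ``1/dy`` (px/mm).  Both > 0.
    skew
        Skew coefficient gamma of the intrinsic matrix (px); 0 for square,
        axis-aligned pixels.
    principal_point
        (u0, v0) in px.
    radial_distortion
        (k1, k2) radial coefficients in mm^-2 / mm^-4.
    """

    focal_length_mm: float
    dx_mm: float
    dy_mm: float
    skew: float = 0.0
    principal_point: tuple[float, float] = (0.0, 0.0)
    radial_distortion: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.focal_length_mm > 0):
            raise ValueError(f"focal length must be > 0, got {self.focal_length_mm}")
        if not (self.dx_mm > 0 and self.dy_mm > 0):
            raise ValueError("pixel pitches dx, dy must be > 0")

    @property
    def alpha(self) -> float:
        """Focal length in horizontal pixels, f/dx."""
        return self.focal_length_mm / self.dx_mm

    @property
    def beta(self) -> float:
        """Focal length in vertical pixels, f/dy."""
        return self.focal_length_mm / self.dy_mm

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 upper-triangular intrinsic matrix A."""
        u0, v0 = self.principal_point
        return np.array(
            [[self.alpha, self.skew, u0], [0.0, self.beta, v0], [0.0, 0.0, 1.0]]
        )

    @property
    def has_distortion(self) -> bool:
        k1, k2 = self.radial_distortion
        return k1 != 0.0 or k2 != 0.0

    @classmethod
    def from_matrix(
        cls,
        a: np.ndarray,
        focal_length_mm: float = 1.0,
        radial_distortion: tuple[float, float] = (0.0, 0.0),
    ) -> "CameraIntrinsics":
        """Build intrinsics from a 3x3 matrix A.

        Only the ratios f/dx, f/dy are identifiable from A, so a focal length
        must be supplied (default 1.0 mm) to factor them into (f, dx, dy).
        """
        a = np.asarray(a, dtype=float)
        if a.shape != (3, 3):
            raise ValueError("intrinsic matrix must be 3x3")
        a = a / a[2, 2]
        return cls(
            focal_length_mm=focal_length_mm,
            dx_mm=focal_length_mm / a[0, 0],
            dy_mm=focal_length_mm / a[1, 1],
            skew=float(a[0, 1]),
            principal_point=(float(a[0, 2]), float(a[1, 2])),
            radial_distortion=radial_distortion,
        )


@dataclass(frozen=True)
class CameraExtrinsics:
    """Camera pose: maps world points into the camera frame, p_c = R p + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (R^T R != I within 1e-9)")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValueError("rotation must have det +1 (proper rotation)")

    @property
    def camera_center(self) -> np.ndarray:
        """Optical centre in world coordinates, C = -R^T t (mm)."""
        return -self.rotation.T @ self.translation


@dataclass(frozen=True)
class ProjectionMatrix:
    """A 3x4 projection matrix M = A [R | t] (pixel = M @ homogeneous world)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 4):
            raise ValueError("projection matrix must be 3x4")
        object.__setattr__(self, "m", m)

    @property
    def camera_center(self) -> np.ndarray:
        """Optical centre in world coordinates (mm)."""
        return -np.linalg.inv(self.m[:, :3]) @ self.m[:, 3]

    def ray_direction(self, pixel: np.ndarray) -> np.ndarray:
        """Unit direction (world frame) of the back-projected ray through *pixel*."""
        u, v = np.asarray(pixel, dtype=float)
        d = np.linalg.inv(self.m[:, :3]) @ np.array([u, v, 1.0])
        return d / np.linalg.norm(d)


def world_to_camera(p: np.ndarray, ext: CameraExtrinsics) -> np.ndarray:
    """Map world points (mm) into the camera frame: p_c = R p + t.

    Accepts a single point ``(3,)`` or a batch ``(N, 3)``.
    """
    p = np.asarray(p, dtype=float)
    return p @ ext.rotation.T + ext.translation


def _distort(xy: np.ndarray, k1: float, k2: float) -> np.ndarray:
    r2 = np.sum(xy**2, axis=-1, keepdims=True)
    return xy * (1.0 + k1 * r2 + k2 * r2**2)


def camera_to_pixel(p: np.ndarray, k: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points (mm) to pixel coordinates.

    Perspective divide by z, scale by f onto the metric image plane, apply
    radial distortion, then the affine pixel mapping.  Raises
    :class:`PointBehindCameraError` when any z <= 0.
    """
    p = np.asarray(p, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise PointBehindCameraError("point at or behind camera (z <= 0)")
    metric = k.focal_length_mm * p[..., :2] / z[..., None]
    return metric_to_pixel(metric, k)


def metric_to_pixel(m: np.ndarray, k: CameraIntrinsics) -> np.ndarray:
    """Map metric image-plane points (mm, undistorted) to pixels.

    Applies radial distortion then the Eq.-style affine mapping
    ``u = x/dx + skew*y/f + u0``, ``v = y/dy + v0`` (equivalently
    pixel = A @ (x/f, y/f, 1)).
    """
    m = np.asarray(m, dtype=float)
    k1, k2 = k.radial_distortion
    d = _distort(m, k1, k2)
    u0, v0 = k.principal_point
    u = d[..., 0] / k.dx_mm + k.skew * d[..., 1] / k.focal_length_mm + u0
    v = d[..., 1] / k.dy_mm + v0
    return np.stack([u, v], axis=-1)


def pixel_to_metric(pix: np.ndarray, k: CameraIntrinsics) -> np.ndarray:
    """Invert :func:`metric_to_pixel`: pixels to undistorted metric mm.

    The affine part is inverted in closed form; radial distortion is removed
    by at most 20 fixed-point iterations (verified by re-distorting).
    """
    pix = np.asarray(pix, dtype=float)
    u0, v0 = k.principal_point
    y_d = (pix[..., 1] - v0) * k.dy_mm
    x_d = (pix[..., 0] - u0 - k.skew * y_d / k.focal_length_mm) * k.dx_mm
    d = np.stack([x_d, y_d], axis=-1)
    if not k.has_distortion:
        return d
    k1, k2 = k.radial_distortion
    xy = d.copy()
    for _ in range(_UNDISTORT_MAX_ITER):
        r2 = np.sum(xy**2, axis=-1, keepdims=True)
        new = d / (1.0 + k1 * r2 + k2 * r2**2)
        step = np.max(np.abs(new - xy))
        xy = new
        if step < _UNDISTORT_TOL_MM:
            break
    if np.max(np.abs(_distort(xy, k1, k2) - d)) > 1e-9:
        raise UndistortionError(
            "radial undistortion did not converge within 20 iterations"
        )
    return xy


def projection_matrix(k: CameraIntrinsics, ext: CameraExtrinsics) -> ProjectionMatrix:
    """Compose the 3x4 projection matrix M = A [R | t]."""
    rt = np.hstack([ext.rotation, ext.translation.reshape(3, 1)])
    return ProjectionMatrix(k.matrix @ rt)


def project_homogeneous(m: ProjectionMatrix, p_world: np.ndarray) -> np.ndarray:
    """Project world points (mm) through M (no distortion): returns pixels.

    Raises :class:`PointBehindCameraError` when the homogeneous depth is <= 0.
    """
    p = np.asarray(p_world, dtype=float)
    ph = np.concatenate([p, np.ones(p.shape[:-1] + (1,))], axis=-1)
    h = ph @ m.m.T
    w = h[..., 2]
    if np.any(w <= 0):
        raise PointBehindCameraError("point at or behind camera (depth <= 0)")
    return h[..., :2] / w[..., None]
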