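"""Planar-target (Zhang) camera calibration.

A planar checkerboard at Z = 0 maps to the image by a homography
``s [u v 1]^T = A [r1 r2 t] [X Y 1]^T``.  Each view's homography is estimated
by the normalised DLT; with at least three views of distinct orientation the
two constraints per view on the image of the absolute conic
``B = A^-T A^-1``::

    h1^T B h2 = 0
    h1^T B h1 = h2^T B h2

yield B (up to scale) by SVD, from which the five intrinsics
(alpha, beta, gamma, u0, v0) follow in closed form and the per-view pose from
``r1 = A^-1 h1 / ||A^-1 h1||`` (with the rotation re-orthonormalised by the
nearest-rotation SVD projection).  No nonlinear refinement is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    project_homogeneous,
    projection_matrix,
)
from .errors import (
    DegenerateConfigurationError,
    InsufficientViewsError,
    NonPositiveDefiniteConicError,
)

__all__ = [
    "Homography",
    "PlanarCorrespondences",
    "estimate_homography",
    "intrinsics_from_homographies",
    "extrinsics_from_homography",
    "CalibrationReport",
    "reprojection_report",
    "read_correspondences_csv",
    "write_correspondences_csv",
]


@dataclass(frozen=True)
class Homography:
    """A 3x3 plane-to-image homography, stored with unit Frobenius norm and
    sign fixed so that h33 >= 0 (when nonzero)."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        h = h / np.linalg.norm(h)
        if h[2, 2] < 0:
            h = -h
        object.__setattr__(self, "h", h)

    def transfer(self, world_xy: np.ndarray) -> np.ndarray:
        """Map (N, 2) plane points (mm) to (N, 2) pixels."""
        w = np.asarray(world_xy, dtype=float)
        ph = np.column_stack([w, np.ones(len(w))]) @ self.h.T
        return ph[:, :2] / ph[:, 2:3]


@dataclass(frozen=True)
class PlanarCorrespondences:
    """Matched target-plane points (X, Y) mm at Z = 0 and their pixels."""

    world_xy: np.ndarray
    pixels: np.ndarray
    view_id: str = ""

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.world_xy, dtype=float))
        p = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        if w.shape != p.shape or w.shape[1] != 2:
            raise ValueError("world_xy and pixels must both be (N, 2)")
        object.__setattr__(self, "world_xy", w)
        object.__setattr__(self, "pixels", p)

    def __len__(self) -> int:
        return len(self.world_xy)


def _normalising_similarity(pts: np.ndarray) -> np.ndarray:
    """Hartley normalisation: translate to centroid, scale to RMS sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    return np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )


def estimate_homography(c: PlanarCorrespondences) -> Homography:
    """Normalised DLT homography from >= 4 non-collinear correspondences.

    Raises :class:`DegenerateConfigurationError` for < 4 points or collinear
    target points.
    """
    n = len(c)
    if n < 4:
        raise DegenerateConfigurationError(
            f"need at least 4 correspondences, got {n}"
        )
    centered = c.world_xy - c.world_xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateConfigurationError("target points are collinear")
    tw = _normalising_similarity(c.world_xy)
    tp = _normalising_similarity(c.pixels)
    wh = np.column_stack([c.world_xy, np.ones(n)]) @ tw.T
    ph = np.column_stack([c.pixels, np.ones(n)]) @ tp.T
    rows = []
    for (x, y, _), (u, v, _) in zip(wh, ph):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    h_norm = vt[-1].reshape(3, 3)
    return Homography(np.linalg.inv(tp) @ h_norm @ tw)


def _conic_row(h: np.ndarray, i: int, j: int) -> np.ndarray:
    """The v_ij vector such that h_i^T B h_j = v_ij . b with
    b = (B11, B12, B22, B13, B23, B33)."""
    hi, hj = h[:, i], h[:, j]
    return np.array(
        [
            hi[0] * hj[0],
            hi[0] * hj[1] + hi[1] * hj[0],
            hi[1] * hj[1],
            hi[2] * hj[0] + hi[0] * hj[2],
            hi[2] * hj[1] + hi[1] * hj[2],
            hi[2] * hj[2],
        ]
    )


def intrinsics_from_homographies(
    hs: list[Homography], focal_length_mm: float = 1.0
) -> CameraIntrinsics:
    """Closed-form intrinsics from >= 3 homographies of distinct poses.

    Solves the stacked absolute-conic constraints for B by SVD and
    decomposes B into the five intrinsics.  Only the intrinsic matrix A is
    identifiable; *focal_length_mm* (default 1.0) factors A into the
    (f, dx, dy) representation.

    Raises :class:`InsufficientViewsError` (< 3 views),
    :class:`DegenerateConfigurationError` (rank-deficient constraints, e.g.
    repeated poses) or :class:`NonPositiveDefiniteConicError`.
    """
    if len(hs) < 3:
        raise InsufficientViewsError(
            f"Zhang calibration needs >= 3 views, got {len(hs)}"
        )
    rows = []
    for hom in hs:
        h = hom.h
        rows.append(_conic_row(h, 0, 1))
        rows.append(_conic_row(h, 0, 0) - _conic_row(h, 1, 1))
    v = np.asarray(rows)
    if np.linalg.matrix_rank(v, tol=1e-8 * np.abs(v).max()) < 5:
        raise DegenerateConfigurationError(
            "constraint matrix is rank-deficient: target poses are degenerate "
            "(e.g. repeated or pure-rotation-free views)"
        )
    _, _, vt = np.linalg.svd(v)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12**2
    if b11 <= 0 or denom <= 0:
        # b is defined up to sign; try the flip before giving up
        b11, b12, b22, b13, b23, b33 = -vt[-1]
        denom = b11 * b22 - b12**2
        if b11 <= 0 or denom <= 0:
            raise NonPositiveDefiniteConicError(
                "estimated absolute-conic image is not positive definite"
            )
    v0 = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam <= 0:
        raise NonPositiveDefiniteConicError(
            "estimated absolute-conic image is not positive definite (lambda <= 0)"
        )
    alpha = np.sqrt(lam / b11)
    beta = np.sqrt(lam * b11 / denom)
    gamma = -b12 * alpha**2 * beta / lam
    u0 = gamma * v0 / beta - b13 * alpha**2 / lam
    a = np.array([[alpha, gamma, u0], [0.0, beta, v0], [0.0, 0.0, 1.0]])
    return CameraIntrinsics.from_matrix(a, focal_length_mm=focal_length_mm)


def extrinsics_from_homography(
    hom: Homography, k: CameraIntrinsics
) -> CameraExtrinsics:
    """Target pose from a homography and known intrinsics.

    ``lambda = 1 / ||A^-1 h1||``, ``r3 = r1 x r2``, rotation projected to the
    nearest orthonormal matrix by SVD, ``t = lambda A^-1 h3``.  The sign is
    fixed so the target sits in front of the camera (t_z > 0).
    """
    a_inv = np.linalg.inv(k.matrix)
    h = hom.h
    lam = 1.0 / np.linalg.norm(a_inv @ h[:, 0])
    if (lam * a_inv @ h[:, 2])[2] < 0:
        lam = -lam
    r1 = lam * a_inv @ h[:, 0]
    r2 = lam * a_inv @ h[:, 1]
    t = lam * a_inv @ h[:, 2]
    r3 = np.cross(r1, r2)
    r_approx = np.column_stack([r1, r2, r3])
    u, _, vt = np.linalg.svd(r_approx)
    r = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    return CameraExtrinsics(rotation=r, translation=t)


@dataclass
class CalibrationReport:
    """Reprojection residuals: per-point table, per-view means, global RMS."""

    points: pd.DataFrame
    per_view_mean: pd.Series
    global_rms: float


def reprojection_report(
    views: list[PlanarCorrespondences],
    k: CameraIntrinsics,
    exts: list[CameraExtrinsics],
) -> CalibrationReport:
    """Reproject each target point through (K, ext) and tabulate residuals."""
    if len(views) != len(exts):
        raise ValueError("one extrinsics per view required")
    frames = []
    for c, ext in zip(views, exts):
        world = np.column_stack([c.world_xy, np.zeros(len(c))])
        m = projection_matrix(k, ext)
        proj = project_homogeneous(m, world)
        res = np.linalg.norm(proj - c.pixels, axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "view_id": c.view_id,
                    "point_index": np.arange(len(c)),
                    "u_obs": c.pixels[:, 0],
                    "v_obs": c.pixels[:, 1],
                    "u_proj": proj[:, 0],
                    "v_proj": proj[:, 1],
                    "residual_px": res,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    per_view = table.groupby("view_id")["residual_px"].mean()
    rms = float(np.sqrt(np.mean(table["residual_px"] ** 2)))
    return CalibrationReport(points=table, per_view_mean=per_view, global_rms=rms)


def read_correspondences_csv(path) -> list[PlanarCorrespondences]:
    """Read corner correspondences from CSV with columns
    view_id, X_mm, Y_mm, u_px, v_px (one row per corner)."""
    df = pd.read_csv(path)
    required = {"view_id", "X_mm", "Y_mm", "u_px", "v_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"correspondence CSV missing columns: {sorted(missing)}")
    out = []
    for view_id, grp in df.groupby("view_id", sort=True):
        out.append(
            PlanarCorrespondences(
                world_xy=grp[["X_mm", "Y_mm"]].to_numpy(),
                pixels=grp[["u_px", "v_px"]].to_numpy(),
                view_id=str(view_id),
            )
        )
    return out


def write_correspondences_csv(views: list[PlanarCorrespondences], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "view_id": c.view_id,
                "X_mm": c.world_xy[:, 0],
                "Y_mm": c.world_xy[:, 1],
                "u_px": c.pixels[:, 0],
                "v_px": c.pixels[:, 1],
            }
        )
        for c in views
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
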