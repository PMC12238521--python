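"""Synthetic refractive stereo scenes: the package's ground-truth generator.

The simulator emulates the measurement experiment end to end: parameterised
3D fish keypoints (a fixed anatomical template scaled to body length, with
seeded shape jitter), a calibrated binocular rig behind a flat port, and the
per-view observations such a rig would record underwater.  For every fish it
produces both the *equivalent-air* projection (straight pinhole geometry, the
oracle for refraction correction) and the *underwater* observation (the air
projection pushed through the forward flat-port map, plus optional Gaussian
pixel noise).

Defaults mirror the target regime: fish of 80–105 mm at 300–700 mm range
(nominally 500 mm), f = 3 mm, glass thickness T = 2.8 mm, indices
n_air/n_glass/n_water = 1.0/1.6/1.33, port at the external focal point
(d = f).  The stereo baseline (60 mm, parallel optical axes) and the sensor
(1280x720, 3 um pixels) are package assumptions chosen so the whole regime
stays in frame in both views.

A planar-checkerboard generator with distinct target orientations supports
the Zhang calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import PlanarCorrespondences
from .camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    metric_to_pixel,
    world_to_camera,
)
from .errors import PointBehindCameraError, RefractionDomainError, TotalInternalReflectionError
from .keypoints import KEYPOINT_NAMES, FishKeypoints, keypoints_bbox
from .refraction import FlatPort, RefractionModel, observe
from .stereo import RigCamera, StereoRig, fish_length

__all__ = [
    "FISH_TEMPLATE",
    "FishPose",
    "FishGroundTruth",
    "SyntheticScene",
    "sample_fish_keypoints",
    "default_intrinsics",
    "default_port",
    "default_rig",
    "render_scene",
    "random_scene",
    "make_checkerboard_views",
]

#: Landmark template in fish-local coordinates, as fractions of body length:
#: x runs mouth -> tail, y is the dorsal direction, z lateral.  The chord from
#: the mouth to the midpoint of the two tail-fin landmarks has length exactly 1.
FISH_TEMPLATE = np.array(
    [
        [0.00, 0.00, 0.0],  # mouth
        [0.12, 0.06, 0.0],  # eye
        [0.35, 0.18, 0.0],  # dorsal_fin1 (anterior end of dorsal fin)
        [0.62, 0.16, 0.0],  # dorsal_fin2 (posterior end)
        [1.00, 0.12, 0.0],  # tail_fin1 (top of tail fin)
        [1.00, -0.12, 0.0],  # tail_fin2 (bottom of tail fin)
        [0.72, -0.14, 0.0],  # anal_fin
        [0.85, 0.08, 0.0],  # top_fin
        [0.38, -0.17, 0.0],  # pelvic_fin
    ]
)

_MOUTH = KEYPOINT_NAMES.index("mouth")
_TAIL1 = KEYPOINT_NAMES.index("tail_fin1")
_TAIL2 = KEYPOINT_NAMES.index("tail_fin2")
#: landmarks free to jitter/bend without touching the mouth-to-tail chord
_INTERIOR = [
    KEYPOINT_NAMES.index(n)
    for n in ("eye", "dorsal_fin1", "dorsal_fin2", "anal_fin", "top_fin", "pelvic_fin")
]

_JITTER_FRACTION = 0.02  # shape jitter bound, fraction of body length


@dataclass(frozen=True)
class FishPose:
    """Rigid placement plus a body-bend parameter.

    yaw/pitch/roll are rotations (rad) about the world y, z and x axes
    applied in that order to the body-centred template; *position* (mm) is
    the world location of the body centre; *bend* laterally bows the interior
    landmarks by up to ``bend * length`` at mid-body (the chord endpoints are
    left in place, so the nominal length is unaffected).
    """

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    bend: float = 0.0
    position: tuple[float, float, float] = (30.0, 0.0, 500.0)


def sample_fish_keypoints(
    length_mm: float,
    pose: FishPose | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a (9, 3) array of world-frame fish landmarks (mm).

    The template is scaled so the mouth-to-tail-fin-midpoint distance equals
    *length_mm* exactly; interior landmarks get seeded uniform jitter up to
    2% of the length, and the two tail fins get mirrored jitter so their
    midpoint (the tail reference point) is preserved.  Deterministic for a
    given seed/rng and independent of the pose.
    """
    if not (50.0 <= length_mm <= 2000.0):
        raise ValueError("length must lie in [50, 2000] mm")
    pose = pose or FishPose()
    rng = rng if rng is not None else np.random.default_rng(seed)
    pts = FISH_TEMPLATE * length_mm
    jit = rng.uniform(-_JITTER_FRACTION, _JITTER_FRACTION, size=(9, 3)) * length_mm
    pts[_INTERIOR] += jit[_INTERIOR]
    pts[_TAIL1] += jit[_TAIL1]
    pts[_TAIL2] -= jit[_TAIL1]  # mirrored: tail midpoint stays put
    if pose.bend != 0.0:
        s = pts[:, 0] / length_mm
        pts[_INTERIOR, 2] += (
            4.0 * pose.bend * length_mm * (s * (1.0 - s))[_INTERIOR]
        )
    centre = np.array([length_mm / 2.0, 0.0, 0.0])
    rot = Rotation.from_euler("yzx", [pose.yaw, pose.pitch, pose.roll])
    return (pts - centre) @ rot.as_matrix().T + np.asarray(pose.position, float)


@dataclass
class FishGroundTruth:
    """True 3D landmarks of one fish and the implied body length."""

    points3d: np.ndarray
    length_mm: float = field(init=False)

    def __post_init__(self) -> None:
        self.points3d = np.asarray(self.points3d, dtype=float)
        if self.points3d.shape != (9, 3):
            raise ValueError("fish ground truth must be (9, 3)")
        tail_mid = 0.5 * (self.points3d[_TAIL1] + self.points3d[_TAIL2])
        self.length_mm = fish_length(self.points3d[_MOUTH], tail_mid)


@dataclass
class SyntheticScene:
    """A rendered stereo scene: rig, ground truth and per-view keypoints."""

    rig: StereoRig
    model: RefractionModel
    fish: list[FishGroundTruth]
    observations: dict[str, list[FishKeypoints]]
    air_equiv: dict[str, list[FishKeypoints]]
    seed: int


def default_intrinsics(
    f_mm: float = 3.0,
    pixel_mm: float = 0.003,
    image_size: tuple[int, int] = (1280, 720),
) -> CameraIntrinsics:
    """A 3 mm lens on a 3 um-pitch sensor, principal point at centre."""
    return CameraIntrinsics(
        focal_length_mm=f_mm,
        dx_mm=pixel_mm,
        dy_mm=pixel_mm,
        principal_point=(image_size[0] / 2.0, image_size[1] / 2.0),
    )


def default_port(f_mm: float = 3.0, t_mm: float = 2.8, tilt_rad: float = 0.0) -> FlatPort:
    """Flat port at the external focal point (d = f), 2.8 mm glass,
    n = 1.0 / 1.6 / 1.33."""
    return FlatPort(d_mm=f_mm, t_mm=t_mm, tilt_rad=tilt_rad)


def default_rig(
    baseline_mm: float = 60.0,
    f_mm: float = 3.0,
    pixel_mm: float = 0.003,
    image_size: tuple[int, int] = (1280, 720),
    t_mm: float = 2.8,
    tilt_rad: float = 0.0,
) -> StereoRig:
    """Parallel-axis binocular rig; world frame = left-camera frame."""
    k = default_intrinsics(f_mm, pixel_mm, image_size)
    port = default_port(f_mm, t_mm, tilt_rad)
    left = RigCamera(intrinsics=k, extrinsics=CameraExtrinsics(), port=port)
    right = RigCamera(
        intrinsics=k,
        extrinsics=CameraExtrinsics(translation=np.array([-baseline_mm, 0.0, 0.0])),
        port=port,
    )
    return StereoRig(left=left, right=right, image_size=image_size)


def _in_frame(pix: np.ndarray, image_size: tuple[int, int]) -> bool:
    w, h = image_size
    return bool(0.0 <= pix[0] < w and 0.0 <= pix[1] < h)


def _observe_metric(
    m: np.ndarray, port: FlatPort, model: RefractionModel
) -> np.ndarray:
    """Forward flat-port map on one metric image point (air -> underwater)."""
    if model is RefractionModel.TILTED:
        from dataclasses import replace

        mx = observe(float(m[0]), port, RefractionModel.TILTED)
        my = observe(float(m[1]), replace(port, tilt_rad=0.0), RefractionModel.PARALLEL)
        return np.array([mx, my])
    r = float(np.hypot(m[0], m[1]))
    if r == 0.0:
        return m.copy()
    return m * (observe(r, port, model) / r)


def render_scene(
    fish_list: list[FishGroundTruth],
    rig: StereoRig,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    model: RefractionModel = RefractionModel.PARALLEL,
) -> SyntheticScene:
    """Render ground-truth fish through the rig, with and without refraction.

    ``air_equiv`` holds the straight pinhole projections; ``observations``
    holds the underwater pixels (forward flat-port map applied radially to
    the metric air coordinates, then seeded N(0, sigma^2) pixel noise).
    Landmarks that fall out of frame or beyond the TIR bound are flagged
    invisible.  Raises :class:`PointBehindCameraError` if any fish is not in
    front of both cameras.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    observations: dict[str, list[FishKeypoints]] = {"left": [], "right": []}
    air_equiv: dict[str, list[FishKeypoints]] = {"left": [], "right": []}
    for name, cam in (("left", rig.left), ("right", rig.right)):
        for idx, fish in enumerate(fish_list):
            p_cam = world_to_camera(fish.points3d, cam.extrinsics)
            if np.any(p_cam[:, 2] <= 0):
                raise PointBehindCameraError(
                    f"fish {idx} is not entirely in front of the {name} camera"
                )
            metric_air = (
                cam.intrinsics.focal_length_mm * p_cam[:, :2] / p_cam[:, 2:3]
            )
            air_px = metric_to_pixel(metric_air, cam.intrinsics)
            air_vis = np.array(
                [1 if _in_frame(p, rig.image_size) else 0 for p in air_px]
            )
            obs_px = np.empty_like(air_px)
            obs_vis = np.ones(9, dtype=int)
            for i in range(9):
                try:
                    m_w = _observe_metric(metric_air[i], cam.port, model)
                except (TotalInternalReflectionError, RefractionDomainError):
                    obs_px[i] = air_px[i]
                    obs_vis[i] = 0
                    continue
                obs_px[i] = metric_to_pixel(m_w, cam.intrinsics)
                if not _in_frame(obs_px[i], rig.image_size):
                    obs_vis[i] = 0
            noise = rng.normal(0.0, 1.0, size=(9, 2))  # drawn even when sigma=0
            if noise_sigma_px > 0:
                obs_px = obs_px + noise_sigma_px * noise
            air_kps = FishKeypoints(xy=air_px, visibility=air_vis)
            air_kps.bbox = keypoints_bbox(air_kps)
            obs_kps = FishKeypoints(xy=obs_px, visibility=obs_vis)
            obs_kps.bbox = keypoints_bbox(obs_kps)
            air_equiv[name].append(air_kps)
            observations[name].append(obs_kps)
    return SyntheticScene(
        rig=rig,
        model=model,
        fish=list(fish_list),
        observations=observations,
        air_equiv=air_equiv,
        seed=seed,
    )


def random_scene(
    seed: int,
    n_fish: int = 1,
    noise_sigma_px: float = 0.0,
    model: RefractionModel = RefractionModel.PARALLEL,
    rig: StereoRig | None = None,
    length_range: tuple[float, float] = (80.0, 105.0),
    z_range: tuple[float, float] = (300.0, 700.0),
) -> SyntheticScene:
    """Draw random fish in the default regime and render them.

    Poses keep the fish roughly broadside to the rig (|yaw| <= 25 deg,
    small pitch/roll/bend) and centred between the cameras so all landmarks
    stay in frame across the 300-700 mm range.
    """
    rig = rig or default_rig()
    ss = np.random.SeedSequence(seed)
    fish_seed, render_seed = ss.spawn(2)
    rng = np.random.default_rng(fish_seed)
    half_base = rig.baseline_mm / 2.0
    fish = []
    for _ in range(n_fish):
        pose = FishPose(
            yaw=rng.uniform(-math.radians(25), math.radians(25)),
            pitch=rng.uniform(-math.radians(8), math.radians(8)),
            roll=rng.uniform(-math.radians(8), math.radians(8)),
            bend=rng.uniform(-0.03, 0.03),
            position=(
                half_base + rng.uniform(-10.0, 10.0),
                rng.uniform(-15.0, 15.0),
                rng.uniform(*z_range),
            ),
        )
        pts = sample_fish_keypoints(rng.uniform(*length_range), pose=pose, rng=rng)
        fish.append(FishGroundTruth(points3d=pts))
    return render_scene(
        fish,
        rig,
        noise_sigma_px=noise_sigma_px,
        seed=int(render_seed.generate_state(1)[0] % (2**31)),
        model=model,
    )


# ---------------------------------------------------------------------------
# Checkerboard views for calibration tests
# ---------------------------------------------------------------------------

# base target orientations (deg, intrinsic xyz) — pairwise >= 10 deg apart
_BOARD_ANGLES_DEG = (
    (25.0, 5.0, 3.0),
    (-5.0, 25.0, -8.0),
    (-20.0, -15.0, 12.0),
    (15.0, -25.0, 5.0),
    (-25.0, 18.0, -10.0),
    (10.0, 20.0, 40.0),
    (30.0, -10.0, -25.0),
    (-15.0, -28.0, 20.0),
)


def make_checkerboard_views(
    k_true: CameraIntrinsics,
    n_views: int = 3,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    board_shape: tuple[int, int] = (8, 6),
    square_mm: float = 25.0,
    distance_mm: float = 400.0,
) -> list[PlanarCorrespondences]:
    """Project a planar checkerboard from *n_views* distinct orientations.

    Corners are exact pinhole projections (no distortion) plus optional
    Gaussian pixel noise; deterministic under a fixed seed.  At most
    ``len(_BOARD_ANGLES_DEG)`` views are available.
    """
    if n_views > len(_BOARD_ANGLES_DEG):
        raise ValueError(f"at most {len(_BOARD_ANGLES_DEG)} distinct views supported")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nx, ny = board_shape
    gx, gy = np.meshgrid(np.arange(nx) * square_mm, np.arange(ny) * square_mm)
    world_xy = np.column_stack([gx.ravel(), gy.ravel()])
    centre = np.array([(nx - 1) * square_mm / 2.0, (ny - 1) * square_mm / 2.0, 0.0])
    views = []
    for i in range(n_views):
        ang = np.radians(_BOARD_ANGLES_DEG[i]) + rng.uniform(-0.03, 0.03, 3)
        r = Rotation.from_euler("xyz", ang).as_matrix()
        target_centre = np.array(
            [rng.uniform(-15.0, 15.0), rng.uniform(-15.0, 15.0),
             distance_mm + rng.uniform(-30.0, 30.0)]
        )
        t = target_centre - r @ centre
        ext = CameraExtrinsics(rotation=r, translation=t)
        world3 = np.column_stack([world_xy, np.zeros(len(world_xy))])
        p_cam = world_to_camera(world3, ext)
        metric = k_true.focal_length_mm * p_cam[:, :2] / p_cam[:, 2:3]
        pixels = metric_to_pixel(metric, k_true)
        if noise_sigma_px > 0:
            pixels = pixels + rng.normal(0.0, noise_sigma_px, pixels.shape)
        views.append(
            PlanarCorrespondences(world_xy=world_xy, pixels=pixels, view_id=f"view{i}")
        )
    return views
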