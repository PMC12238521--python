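import numpy as np
import pytest

from fishstereo.camera import CameraIntrinsics
from fishstereo.refraction import FlatPort
from fishstereo.simulate import default_intrinsics, default_rig


@pytest.fixture
def port() -> FlatPort:
    """The reference flat port: d = f = 3 mm, T = 2.8 mm, n = 1/1.6/1.33."""
    return FlatPort(d_mm=3.0, t_mm=2.8)


@pytest.fixture
def intrinsics() -> CameraIntrinsics:
    return default_intrinsics()


@pytest.fixture
def rig():
    return default_rig()


def midpoint_triangulate(p_left, p_right, m1, m2) -> np.ndarray:
    """Independent closed-form triangulation oracle.

    Back-projects both pixels to rays and returns the midpoint of the common
    perpendicular segment between the two skew lines.
    """
    c1, d1 = m1.camera_center, m1.ray_direction(p_left)
    c2, d2 = m2.camera_center, m2.ray_direction(p_right)
    w = c2 - c1
    a = np.array([[d1 @ d1, -(d1 @ d2)], [d1 @ d2, -(d2 @ d2)]])
    b = np.array([w @ d1, w @ d2])
    s, t = np.linalg.solve(a, b)
    return 0.5 * (c1 + s * d1 + c2 + t * d2)
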