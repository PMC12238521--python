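import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import midpoint_triangulate
from fishstereo.camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    project_homogeneous,
    projection_matrix,
)
from fishstereo.errors import DegenerateGeometryError, MissingKeypointError
from fishstereo.keypoints import KEYPOINT_NAMES, FishKeypoints
from fishstereo.refraction import RefractionModel
from fishstereo.simulate import FishGroundTruth, FishPose, render_scene, sample_fish_keypoints
from fishstereo.stereo import (
    ErrorStats,
    fish_length,
    measure_fish,
    mrpe,
    relative_error,
    triangulate,
)


def random_rig_matrices(rng):
    """A random valid stereo pair of projection matrices."""
    k = CameraIntrinsics(
        focal_length_mm=rng.uniform(2, 5),
        dx_mm=rng.uniform(0.002, 0.005),
        dy_mm=rng.uniform(0.002, 0.005),
        principal_point=tuple(rng.uniform(200, 500, 2)),
    )
    m1 = projection_matrix(k, CameraExtrinsics())
    r = Rotation.from_euler("xyz", rng.uniform(-0.1, 0.1, 3)).as_matrix()
    t = np.array([-rng.uniform(40, 120), rng.uniform(-5, 5), rng.uniform(-5, 5)])
    m2 = projection_matrix(k, CameraExtrinsics(rotation=r, translation=t))
    return m1, m2


class TestTriangulate:
    def test_hand_checkable_rig(self):
        k = CameraIntrinsics(1.0, 1.0, 1.0)
        m1 = projection_matrix(k, CameraExtrinsics())
        m2 = projection_matrix(
            k, CameraExtrinsics(translation=(-100.0, 0.0, 0.0))
        )
        # point (50, 0, 500): left pixel (0.1, 0), right pixel (-0.1, 0)
        p = triangulate(np.array([0.1, 0.0]), np.array([-0.1, 0.0]), m1, m2)
        assert np.allclose(p, (50, 0, 500), atol=1e-9)

    def test_recovers_random_points(self):
        rng = np.random.default_rng(12)
        worst = 0.0
        for _ in range(50):
            m1, m2 = random_rig_matrices(rng)
            pts = rng.uniform((-80, -60, 250), (80, 60, 750), size=(20, 3))
            for p in pts:
                est = triangulate(
                    project_homogeneous(m1, p), project_homogeneous(m2, p), m1, m2
                )
                worst = max(worst, float(np.max(np.abs(est - p))))
        assert worst < 1e-6

    def test_agrees_with_midpoint_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m1, m2 = random_rig_matrices(rng)
            p = rng.uniform((-50, -40, 300), (50, 40, 600))
            pl, pr = project_homogeneous(m1, p), project_homogeneous(m2, p)
            assert np.allclose(
                triangulate(pl, pr, m1, m2), midpoint_triangulate(pl, pr, m1, m2),
                atol=1e-9,
            )

    def test_identical_cameras_degenerate(self):
        k = CameraIntrinsics(3.0, 0.003, 0.003)
        m = projection_matrix(k, CameraExtrinsics())
        with pytest.raises(DegenerateGeometryError):
            triangulate(np.array([1.0, 2.0]), np.array([1.0, 2.0]), m, m)


class TestFishLength:
    @pytest.mark.parametrize(
        "head,tail,expected",
        [((0, 0, 0), (82.8, 0, 0), 82.8), ((0, 0, 0), (3, 4, 12), 13.0)],
    )
    def test_euclidean_distance(self, head, tail, expected):
        assert fish_length(np.array(head, float), np.array(tail, float)) == pytest.approx(expected)
        assert fish_length(np.array(tail, float), np.array(head, float)) == pytest.approx(expected)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        h, t = rng.normal(size=3) * 50, rng.normal(size=3) * 50
        r = Rotation.from_euler("zyx", rng.uniform(-1, 1, 3)).as_matrix()
        shift = rng.normal(size=3) * 100
        assert fish_length(r @ h + shift, r @ t + shift) == pytest.approx(
            fish_length(h, t), rel=1e-12
        )


class TestErrorStats:
    @pytest.mark.parametrize(
        "lt,la,expected", [(82.8, 82.8, 0.0), (103.0, 100.0, 3.0), (97.0, 100.0, 3.0)]
    )
    def test_relative_error(self, lt, la, expected):
        assert relative_error(lt, la) == pytest.approx(expected)

    def test_relative_error_needs_positive_reference(self):
        with pytest.raises(ValueError):
            relative_error(10.0, 0.0)

    def test_mrpe(self):
        assert mrpe([(100.0, 100.0)]) == 0.0
        assert mrpe([(102.0, 100.0), (104.0, 100.0)]) == pytest.approx(3.0)
        pairs = [(102.0, 100.0), (95.0, 100.0), (100.5, 100.0)]
        assert mrpe(pairs) == pytest.approx(mrpe(pairs[::-1]))

    def test_mrpe_empty_rejected(self):
        with pytest.raises(ValueError):
            mrpe([])

    def test_stats_mean_consistency(self):
        stats = ErrorStats.from_lengths([101.0, 97.0], [100.0, 100.0])
        assert stats.mrpe == pytest.approx(np.mean(stats.re_list), abs=1e-12)
        assert all(re >= 0 for re in stats.re_list)


class TestMeasureFish:
    def _scene(self, length=90.0, **render_kw):
        pts = sample_fish_keypoints(length, FishPose(yaw=0.3, position=(30, 0, 500)),
                                    seed=5)
        fish = FishGroundTruth(points3d=pts)
        from fishstereo.simulate import default_rig

        return fish, render_scene([fish], default_rig(), **render_kw)

    def test_noiseless_length_recovery(self):
        fish, scene = self._scene(length=90.0)
        meas = measure_fish(
            scene.observations["left"][0],
            scene.observations["right"][0],
            scene.rig,
            model=RefractionModel.PARALLEL,
        )
        assert fish.length_mm == pytest.approx(90.0, abs=1e-9)
        assert meas.length_mm == pytest.approx(fish.length_mm, rel=1e-6)
        assert meas.length_mm == pytest.approx(
            fish_length(meas.head_point, meas.tail_point), abs=1e-12
        )
        assert len(meas.points3d) == 9
        assert max(meas.residuals_px.values()) < 1e-6

    def test_triangulated_points_match_ground_truth(self):
        fish, scene = self._scene()
        meas = measure_fish(
            scene.observations["left"][0], scene.observations["right"][0],
            scene.rig, model=RefractionModel.PARALLEL,
        )
        for i, name in enumerate(KEYPOINT_NAMES):
            assert np.allclose(meas.points3d[name], fish.points3d[i], atol=1e-5)

    def test_skipping_correction_biases_length(self):
        fish, scene = self._scene()
        raw = measure_fish(
            scene.observations["left"][0], scene.observations["right"][0],
            scene.rig, model=None,
        )
        assert abs(raw.length_mm - fish.length_mm) > 0.1

    def test_missing_mouth_raises(self):
        _, scene = self._scene()
        right = scene.observations["right"][0]
        broken = FishKeypoints(xy=right.xy.copy(),
                               visibility=right.visibility.copy())
        broken.visibility[KEYPOINT_NAMES.index("mouth")] = 0
        with pytest.raises(MissingKeypointError):
            measure_fish(scene.observations["left"][0], broken, scene.rig)

    def test_missing_both_tail_fins_raises(self):
        _, scene = self._scene()
        right = scene.observations["right"][0]
        broken = FishKeypoints(xy=right.xy.copy(),
                               visibility=right.visibility.copy())
        for name in ("tail_fin1", "tail_fin2"):
            broken.visibility[KEYPOINT_NAMES.index(name)] = 0
        with pytest.raises(MissingKeypointError):
            measure_fish(scene.observations["left"][0], broken, scene.rig)

    def test_tail_rule_selection(self):
        fish, scene = self._scene()
        kl = scene.observations["left"][0]
        kr = scene.observations["right"][0]
        for rule, idx in (("tail_fin1", 4), ("tail_fin2", 5)):
            meas = measure_fish(kl, kr, scene.rig, tail_rule=rule)
            expected = fish_length(fish.points3d[0], fish.points3d[idx])
            assert meas.length_mm == pytest.approx(expected, rel=1e-6)
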