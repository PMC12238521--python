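import math
from dataclasses import replace

import numpy as np
import pytest

from fishstereo.camera import pixel_to_metric
from fishstereo.errors import (
    PortGeometryError,
    TotalInternalReflectionError,
)
from fishstereo.keypoints import FishKeypoints
from fishstereo.refraction import (
    FlatPort,
    RefractionModel,
    correct,
    correct_keypoints,
    correct_parallel,
    correct_single,
    correct_tilted,
    magnification_ratio,
    observe,
    observe_keypoints,
    observe_parallel,
    observe_single,
    observe_tilted,
    snell_refract,
)
from fishstereo.simulate import default_intrinsics

MODELS = list(RefractionModel)


def model_port(model: RefractionModel) -> FlatPort:
    tilt = math.radians(2.0) if model is RefractionModel.TILTED else 0.0
    return FlatPort(d_mm=3.0, t_mm=2.8, tilt_rad=tilt)


class TestSnell:
    def test_normal_incidence_passes_straight(self):
        for n1, n2 in [(1.0, 1.33), (1.33, 1.0), (1.6, 1.33)]:
            assert snell_refract(0.0, n1, n2) == 0.0

    def test_water_to_air_at_30_degrees(self):
        out = snell_refract(math.radians(30), 1.33, 1.0)
        # arcsin(1.33 * 0.5) = arcsin(0.665)
        assert math.degrees(out) == pytest.approx(41.6823254, abs=1e-6)

    def test_total_internal_reflection(self):
        # 1.33 * sin(60 deg) = 1.1518 > 1
        with pytest.raises(TotalInternalReflectionError):
            snell_refract(math.radians(60), 1.33, 1.0)


class TestSingleModel:
    def test_axial_ray_fixed(self, port):
        assert correct_single(0.0, port) == 0.0
        assert observe_single(0.0, port) == 0.0

    def test_hand_evaluated_correction(self):
        # d=3, x_r=3: arctan(1)=45deg, arcsin(sin45/1.33)=0.560596 rad
        port = FlatPort(d_mm=3.0, t_mm=0.0)
        assert correct_single(3.0, port) == pytest.approx(1.8831831438, abs=1e-9)

    def test_small_angle_limit_is_index_ratio(self, port):
        x = 1e-7
        assert correct_single(x, port) / x == pytest.approx(1 / 1.33, rel=1e-9)

    def test_identity_when_indices_match(self):
        port = FlatPort(d_mm=3.0, t_mm=2.8, n_water=1.0)
        for x in np.linspace(-2, 2, 41):
            assert correct_single(x, port) == pytest.approx(x, abs=1e-12)

    def test_observe_tir(self, port):
        # x_a beyond d*tan(critical angle) has no underwater counterpart
        x_max = port.d_mm * math.tan(port.critical_angle)
        with pytest.raises(TotalInternalReflectionError):
            observe_single(x_max + 0.1, port)


class TestParallelModel:
    def test_direct_evaluation_at_known_angle(self, port):
        # independent oracle: evaluate both coordinate equations at alpha=20deg
        a = math.radians(20)
        x_a = 2.8 * math.tan(math.asin(math.sin(a) / 1.6)) + 0.2 * math.tan(a)
        x_r = 2.8 * math.tan(math.asin(1.33 * math.sin(a) / 1.6)) + 0.2 * math.tan(
            math.asin(1.33 * math.sin(a))
        )
        assert x_a == pytest.approx(0.6854914, abs=1e-6)
        assert x_r == pytest.approx(0.9324743, abs=1e-6)
        assert observe_parallel(x_a, port) == pytest.approx(x_r, abs=1e-9)
        assert correct_parallel(x_r, port) == pytest.approx(x_a, abs=1e-9)

    def test_monotone_in_coordinate(self, port):
        xs = np.linspace(0.01, 1.5, 50)
        out = [observe_parallel(x, port) for x in xs]
        assert np.all(np.diff(out) > 0)

    def test_beyond_tir_raises(self, port):
        with pytest.raises(TotalInternalReflectionError):
            correct_parallel(1e7, port)

    def test_reduces_to_single_when_glass_vanishes(self):
        port = FlatPort(d_mm=3.0, t_mm=0.0)
        for x in np.linspace(-1.5, 1.5, 101):
            assert correct_parallel(x, port) == pytest.approx(
                correct_single(x, port), abs=1e-9
            )


class TestTiltedModel:
    def test_zero_tilt_equals_parallel(self, port):
        tilted = replace(port, tilt_rad=0.0)
        for x in np.linspace(-1.5, 1.5, 101):
            assert correct_tilted(x, tilted) == pytest.approx(
                correct_parallel(x, port), abs=1e-12
            )
            assert observe_tilted(x, tilted) == pytest.approx(
                observe_parallel(x, port), abs=1e-12
            )

    def test_converges_to_parallel_as_tilt_shrinks(self, port):
        x = 1.0
        ref = correct_parallel(x, port)
        diffs = [
            abs(correct_tilted(x, replace(port, tilt_rad=b)) - ref)
            for b in (0.04, 0.02, 0.01, 0.005)
        ]
        assert all(a > b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 0.01

    def test_geometry_error_when_port_too_close(self):
        port = FlatPort(d_mm=2.81, t_mm=2.8, tilt_rad=math.radians(10))
        with pytest.raises(PortGeometryError):
            correct_tilted(0.5, port)


class TestInversePairs:
    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.value)
    def test_roundtrip_both_directions(self, model):
        port = model_port(model)
        rng = np.random.default_rng(42)
        xs = rng.uniform(-1.5, 1.5, 500)
        for x in xs:
            assert correct(observe(x, port, model), port, model) == pytest.approx(
                x, abs=1e-9
            )
            assert observe(correct(x, port, model), port, model) == pytest.approx(
                x, abs=1e-9
            )

    @pytest.mark.parametrize(
        "model", [RefractionModel.SINGLE, RefractionModel.PARALLEL],
        ids=lambda m: m.value,
    )
    def test_odd_symmetry(self, model, port):
        for x in (0.05, 0.4, 1.2):
            assert observe(-x, port, model) == pytest.approx(
                -observe(x, port, model), abs=1e-12
            )
            assert correct(-x, port, model) == pytest.approx(
                -correct(x, port, model), abs=1e-12
            )

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.value)
    def test_underwater_magnifies(self, model):
        port = model_port(model)
        for x in np.linspace(0.05, 1.2, 20):
            assert observe(x, port, model) > x  # x_r >= x_a for n_water > n_air


class TestMagnification:
    def test_small_angle_single_is_index_ratio(self, port):
        ratio = magnification_ratio(1e-8, port, RefractionModel.SINGLE)
        assert ratio == pytest.approx(1.33, abs=1e-9)

    @pytest.mark.parametrize(
        "model", [RefractionModel.SINGLE, RefractionModel.PARALLEL],
        ids=lambda m: m.value,
    )
    def test_strictly_increasing_pincushion(self, model, port):
        alphas = np.linspace(port.critical_angle / 100, port.critical_angle - 1e-6, 200)
        ratios = [magnification_ratio(a, port, model) for a in alphas]
        assert np.all(np.diff(ratios) > 0)

    def test_secondary_refraction_reduces_magnification(self, port):
        alphas = np.linspace(0.01, port.critical_angle - 1e-6, 100)
        for a in alphas:
            assert magnification_ratio(
                a, port, RefractionModel.PARALLEL
            ) < magnification_ratio(a, port, RefractionModel.SINGLE)

    def test_out_of_domain_angle_raises(self, port):
        with pytest.raises(TotalInternalReflectionError):
            magnification_ratio(port.critical_angle + 0.01, port,
                                RefractionModel.SINGLE)


class TestKeypointCorrection:
    def _kps(self, xy, vis=None):
        xy = np.asarray(xy, float)
        vis = np.ones(9, int) if vis is None else np.asarray(vis, int)
        return FishKeypoints(xy=xy, visibility=vis)

    def test_principal_point_unchanged(self, port, intrinsics):
        pp = np.array(intrinsics.principal_point)
        xy = np.tile(pp, (9, 1))
        out = correct_keypoints(self._kps(xy), intrinsics, port)
        assert np.allclose(out.xy, xy)

    def test_azimuth_preserved(self, port, intrinsics):
        rng = np.random.default_rng(5)
        pp = np.array(intrinsics.principal_point)
        xy = pp + rng.uniform(-250, 250, size=(9, 2))
        out = correct_keypoints(self._kps(xy), intrinsics, port)
        for before, after in zip(xy, out.xy):
            mb = pixel_to_metric(before, intrinsics)
            ma = pixel_to_metric(after, intrinsics)
            if np.hypot(*mb) > 1e-9:
                assert math.atan2(mb[1], mb[0]) == pytest.approx(
                    math.atan2(ma[1], ma[0]), abs=1e-12
                )

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.value)
    def test_observe_then_correct_is_identity(self, model, intrinsics):
        port = model_port(model)
        rng = np.random.default_rng(9)
        pp = np.array(intrinsics.principal_point)
        xy = pp + rng.uniform(-200, 200, size=(9, 2))
        kps = self._kps(xy)
        under = observe_keypoints(kps, intrinsics, port, model)
        back = correct_keypoints(under, intrinsics, port, model)
        assert np.max(np.abs(back.xy - xy)) < 1e-6

    def test_invisible_keypoints_pass_through(self, port, intrinsics):
        xy = np.tile([100.0, 100.0], (9, 1))
        vis = np.zeros(9, int)
        out = correct_keypoints(self._kps(xy, vis), intrinsics, port)
        assert np.array_equal(out.xy, xy)
        assert np.array_equal(out.visibility, vis)

    def test_tir_marks_keypoint_invisible(self, intrinsics):
        # shrink the valid field so an edge keypoint exceeds the TIR bound
        port = FlatPort(d_mm=0.05, t_mm=0.04)
        pp = np.array(intrinsics.principal_point)
        xy = np.tile(pp, (9, 1))
        xy[3] = pp + np.array([600.0, 0.0])  # 1.8 mm metric >> attainable range
        out = observe_keypoints(self._kps(xy), intrinsics, port,
                                RefractionModel.PARALLEL)
        assert out.visibility[3] == 0
        assert out.visibility.sum() == 8


class TestCorrectionGrid:
    def test_grid_matches_pointwise_correction(self, port, intrinsics):
        from fishstereo.refraction import correction_grid

        src, corr = correction_grid(
            intrinsics, port, RefractionModel.PARALLEL, (1280, 720), step=180
        )
        assert src.shape == corr.shape
        # centre sample: principal point maps to itself
        pp = np.array(intrinsics.principal_point)
        flat_src = src.reshape(-1, 2)
        flat_corr = corr.reshape(-1, 2)
        for s, c in zip(flat_src, flat_corr):
            if np.any(np.isnan(c)):
                continue
            m = pixel_to_metric(s, intrinsics)
            r = np.hypot(*m)
            if r < 1e-9:
                assert np.allclose(c, pp)
            else:
                # corrected point is pulled toward the principal point
                mc = pixel_to_metric(c, intrinsics)
                assert np.hypot(*mc) < r


class TestFlatPortValidation:
    def test_rejects_glass_thicker_than_standoff(self):
        with pytest.raises(ValueError):
            FlatPort(d_mm=2.0, t_mm=2.8)

    def test_rejects_subunity_index(self):
        with pytest.raises(ValueError):
            FlatPort(d_mm=3.0, t_mm=2.8, n_water=0.9)

    def test_critical_angle(self, port):
        assert port.critical_angle == pytest.approx(math.asin(1 / 1.33))
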