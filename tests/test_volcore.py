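"""Calibration, segmentation, VOI resolution and rigid registration."""

import numpy as np
import pytest

from osteotrack import synthgen
from osteotrack.volcore import (
    DensityVolume,
    RigidTransform,
    VOISpec,
    apply_transform,
    calibrate_density,
    hu_calibrate,
    register_rigid,
    resolve_voi,
    round_half_away,
    segment,
)


def _vol(values, vox=18.0, cal="raw"):
    return DensityVolume(np.asarray(values, dtype=float), vox, cal)


class TestCalibration:
    def test_anchor_points_map_exactly(self):
        raw = _vol(np.full((2, 2, 2), 40.0))
        out = calibrate_density(raw, (40.0, 250.0), (140.0, 750.0))
        assert out.calibration == "HA"
        assert np.allclose(out.values, 250.0)

    def test_midpoint_is_linear(self):
        raw = _vol(np.full((2, 2, 2), 90.0))
        out = calibrate_density(raw, (40.0, 250.0), (140.0, 750.0))
        assert np.allclose(out.values, 500.0)

    def test_round_trip_inverse(self, rng):
        vals = rng.uniform(0, 200, (4, 4, 4))
        out = calibrate_density(_vol(vals), (40.0, 250.0), (140.0, 750.0))
        m = out.meta["calibration_map"]
        back = (out.values - m["intercept"]) / m["slope"]
        assert np.allclose(back, vals)

    def test_equal_phantom_raws_rejected(self):
        with pytest.raises(ValueError):
            calibrate_density(_vol(np.zeros((2, 2, 2))), (50.0, 250.0), (50.0, 750.0))

    @pytest.mark.parametrize(
        "raw,expected", [(110.0, 0.0), (10.0, -1000.0), (60.0, -500.0)]
    )
    def test_hu_anchors_and_interpolation(self, raw, expected):
        out = hu_calibrate(_vol(np.full((2, 2, 2), raw)), air_mean=10.0, water_mean=110.0)
        assert out.calibration == "HU"
        assert np.allclose(out.values, expected)

    def test_hu_rejects_air_above_water(self):
        with pytest.raises(ValueError):
            hu_calibrate(_vol(np.zeros((2, 2, 2))), 110.0, 10.0)


class TestSegment:
    def test_uniform_volume_thresholds(self):
        vol = _vol(np.full((3, 3, 3), 500.0), cal="HA")
        assert segment(vol, 300.0).all()
        assert not segment(vol, 700.0).any()

    def test_requires_ha_calibration(self):
        with pytest.raises(ValueError):
            segment(_vol(np.zeros((2, 2, 2)), cal="HU"), 300.0)

    def test_phantom_fraction_matches_construction(self, trabecular_phantom):
        vol, truth = trabecular_phantom
        assert segment(vol, 300.0).mean() == pytest.approx(truth.true_bvtv)

    def test_invariant_under_consistent_affine_rescaling(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        raw = _vol(vol.values * 0.3 + 17.0, cal="raw")
        # phantom values 0/600 HA <-> raw anchors transformed consistently
        cal = calibrate_density(raw, (0.3 * 250 + 17, 250.0), (0.3 * 750 + 17, 750.0))
        assert np.array_equal(segment(cal, 300.0), segment(vol, 300.0))


class TestVOI:
    def test_trabecular_window_18um(self):
        vol = _vol(np.zeros((400, 4, 4)), vox=18.0, cal="HA")
        (start, stop), crop = resolve_voi(vol, VOISpec(100, 0.5, 2.0))
        assert start == 128  # 500/18 = 27.8 -> 28
        assert stop - start == 111  # 2000/18 = 111.1 -> 111
        assert crop.shape[0] == 111

    def test_cortical_centred_window_7um(self):
        vol = _vol(np.zeros((600, 4, 4)), vox=7.0, cal="HA")
        (start, stop), _ = resolve_voi(vol, VOISpec(50, 3.0, 0.5, centered=True))
        assert stop - start == 71  # 500/7 = 71.4 -> 71
        assert (start + stop) // 2 - 50 == 429  # 3000/7 = 428.6 -> 429

    def test_single_slice_window(self):
        vol = _vol(np.zeros((50, 4, 4)), vox=18.0, cal="HA")
        (start, stop), crop = resolve_voi(vol, VOISpec(10, 0.0, 0.018))
        assert (start, stop) == (10, 11)

    def test_out_of_range_rejected(self):
        vol = _vol(np.zeros((50, 4, 4)), vox=18.0, cal="HA")
        with pytest.raises(ValueError):
            resolve_voi(vol, VOISpec(40, 0.5, 2.0))

    @pytest.mark.parametrize("x,expected", [(27.78, 28), (111.1, 111), (-27.5, -28), (0.5, 1)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        tf = RigidTransform((5.0, -3.0, 2.0), (30.0, -20.0, 10.0))
        inv = tf.inverse()
        r = tf.rotation_matrix() @ inv.rotation_matrix()
        assert np.allclose(r, np.eye(3), atol=1e-12)
        t = tf.rotation_matrix() @ np.asarray(inv.translation_um) + np.asarray(tf.translation_um)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_json_round_trip(self):
        tf = RigidTransform((1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        assert RigidTransform.from_dict(tf.to_dict()).params() == pytest.approx(tf.params())


class TestRegisterRigid:
    def test_identity_for_equal_volumes(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        tf, res = register_rigid(vol, vol)
        assert np.abs(tf.params()[:3]).max() < 0.1
        assert np.abs(np.asarray(tf.translation_um) / vol.voxel_size_um).max() < 0.1

    def test_known_transform_recovered(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        tf_true = RigidTransform((5.0, 0.0, 0.0), (5 * 18.0, -2 * 18.0, 3 * 18.0))
        moved = apply_transform(vol, tf_true)
        # registering the moved scan back must find the inverse transform
        tf, _ = register_rigid(moved, vol)
        expect = tf_true.inverse()
        assert np.abs(np.asarray(tf.angles_deg) - expect.angles_deg).max() < 0.5
        t_err = (np.asarray(tf.translation_um) - expect.translation_um) / 18.0
        assert np.abs(t_err).max() < 0.5

    def test_inverse_consistency(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        tf_true = RigidTransform((0.0, 3.0, 0.0), (2 * 18.0, 18.0, -2 * 18.0))
        moved = apply_transform(vol, tf_true)
        tf_ab, _ = register_rigid(moved, vol)
        tf_ba, _ = register_rigid(vol, moved)
        comp_r = tf_ab.rotation_matrix() @ tf_ba.rotation_matrix()
        assert np.abs(comp_r - np.eye(3)).max() < 0.02
        comp_t = tf_ba.rotation_matrix() @ np.asarray(tf_ab.translation_um) + np.asarray(
            tf_ba.translation_um
        )
        assert np.abs(comp_t / 18.0).max() < 0.5

    def test_refinement_improves_or_matches_ncc(self, trabecular_phantom):
        from osteotrack.volcore import _ncc

        vol, _ = trabecular_phantom
        tf_true = RigidTransform((0.0, 0.0, 4.0), (2 * 18.0, -3 * 18.0, 18.0))
        moved = apply_transform(vol, tf_true)
        _, res = register_rigid(moved, vol)
        assert _ncc(vol.values, res.values) >= _ncc(vol.values, moved.values)

    def test_empty_mask_rejected(self):
        flat = _vol(np.zeros((34, 34, 34)), cal="HA")
        with pytest.raises(ValueError):
            register_rigid(flat, flat, threshold=100.0)
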