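"""Gravity compensation, axis rotation, rolling filters and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signglove import imu_preprocess as imu
from signglove import synthetic_data as sd


def quat_rotate_oracle(q, v):
    """Independent sandwich-product oracle: rotate v by q via q v q*."""
    w, x, y, z = q
    qv = np.array([0.0, *v])
    qc = np.array([w, -x, -y, -z])

    def mul(a, b):
        w1, x1, y1, z1 = a
        w2, x2, y2, z2 = b
        return np.array(
            [
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            ]
        )

    return mul(mul(q, qv), qc)[1:]


def random_unit_quats(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class TestGravityVector:
    @pytest.mark.parametrize(
        "q,expected",
        [
            ((1, 0, 0, 0), (0, 0, 9.81)),
            ((0, 1, 0, 0), (0, 0, -9.81)),
            ((np.sqrt(2) / 2, 0, np.sqrt(2) / 2, 0), (-9.81, 0, 0)),
        ],
    )
    def test_known_orientations(self, q, expected):
        np.testing.assert_allclose(
            imu.gravity_vector(np.array(q, float), 9.81), expected, atol=1e-9
        )

    def test_matches_conjugate_rotation_oracle(self, rng):
        # gravity in the body frame is (0,0,g) rotated by the conjugate quat
        for q in random_unit_quats(rng, 20):
            qc = q * np.array([1.0, -1, -1, -1])
            expected = quat_rotate_oracle(qc, np.array([0.0, 0.0, 9.81]))
            np.testing.assert_allclose(
                imu.gravity_vector(q, 9.81), expected, atol=1e-9
            )

    def test_norm_equals_g_mag(self, rng):
        g = imu.gravity_vector(random_unit_quats(rng, 200), 9.81)
        np.testing.assert_allclose(np.linalg.norm(g, axis=1), 9.81, atol=1e-9)

    def test_zero_quaternion_raises(self):
        with pytest.raises(ValueError):
            imu.gravity_vector(np.zeros(4))

    def test_non_unit_quaternion_warns_and_normalizes(self):
        with pytest.warns(UserWarning):
            g = imu.gravity_vector(np.array([2.0, 0, 0, 0]))
        np.testing.assert_allclose(g, (0, 0, 9.81), atol=1e-9)

    def test_nonpositive_g_raises(self):
        with pytest.raises(ValueError):
            imu.gravity_vector(np.array([1.0, 0, 0, 0]), g_mag=0.0)


class TestCompensateGravity:
    def test_identity_orientation_removes_static_reading(self):
        n = 10
        a = np.tile([0.0, 0.0, 9.81], (n, 1))
        q = np.tile([1.0, 0, 0, 0], (n, 1))
        np.testing.assert_allclose(imu.compensate_gravity(a, q), 0.0, atol=1e-12)

    def test_motion_component_passes_through(self):
        n = 5
        a = np.tile([1.0, 0.0, 9.81], (n, 1))
        q = np.tile([1.0, 0, 0, 0], (n, 1))
        la = imu.compensate_gravity(a, q)
        np.testing.assert_allclose(la, np.tile([1.0, 0, 0], (n, 1)), atol=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            imu.compensate_gravity(np.zeros((5, 3)), np.tile([1.0, 0, 0, 0], (4, 1)))

    def test_simulator_roundtrip_recovers_truth(self, noiseless_profile):
        for template in sd.dynamic_templates():
            rec = sd.forward_model(template, noiseless_profile)
            la = imu.compensate_gravity(rec.accel_body, rec.quat)
            earth = imu.rotate_to_earth(la, rec.quat)
            np.testing.assert_allclose(
                earth, rec.meta["truth"]["accel_earth"], atol=1e-6
            )


class TestQuaternionToRotation:
    def test_identity(self):
        np.testing.assert_allclose(
            imu.quaternion_to_rotation(np.array([1.0, 0, 0, 0])), np.eye(3),
            atol=1e-12,
        )

    def test_90deg_about_z_against_sandwich_oracle(self):
        q = np.array([np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)])
        r = imu.quaternion_to_rotation(q)
        v = np.array([1.0, 0, 0])
        np.testing.assert_allclose(r @ v, [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(r @ v, quat_rotate_oracle(q, v), atol=1e-12)

    def test_random_quats_match_sandwich_oracle(self, rng):
        for q in random_unit_quats(rng, 20):
            r = imu.quaternion_to_rotation(q)
            v = rng.normal(size=3)
            np.testing.assert_allclose(r @ v, quat_rotate_oracle(q, v), atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=4, max_size=4))
    def test_orthonormality_and_det(self, comps):
        q = np.asarray(comps)
        norm = np.linalg.norm(q)
        if norm < 1e-3:
            return
        r = imu.quaternion_to_rotation(q / norm)
        np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(r) - 1.0) < 1e-9

    def test_sign_ambiguity_is_invariant(self, rng):
        q = random_unit_quats(rng, 1)[0]
        np.testing.assert_allclose(
            imu.quaternion_to_rotation(q), imu.quaternion_to_rotation(-q),
            atol=1e-12,
        )


class TestRotateToEarth:
    def test_identity_orientation_is_noop(self, rng):
        la = rng.normal(size=(8, 3))
        q = np.tile([1.0, 0, 0, 0], (8, 1))
        np.testing.assert_allclose(imu.rotate_to_earth(la, q), la, atol=1e-12)

    def test_90deg_about_z(self):
        la = np.tile([1.0, 0, 0], (4, 1))
        q = np.tile([np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)], (4, 1))
        np.testing.assert_allclose(
            imu.rotate_to_earth(la, q), np.tile([0, 1.0, 0], (4, 1)), atol=1e-9
        )

    def test_norm_preserved(self, rng):
        la = rng.normal(size=(50, 3))
        q = random_unit_quats(rng, 50)
        out = imu.rotate_to_earth(la, q)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1), np.linalg.norm(la, axis=1), atol=1e-9
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            imu.rotate_to_earth(np.zeros((3, 3)), np.tile([1.0, 0, 0, 0], (2, 1)))


class TestRollingFilters:
    def test_constant_series_unchanged(self):
        x = np.full(40, 3.5)
        np.testing.assert_allclose(imu.rolling_median(x, 10), x)
        np.testing.assert_allclose(imu.moving_average(x, 10), x)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(imu.rolling_median(x, 1), x)
        np.testing.assert_allclose(imu.moving_average(x, 1), x)

    def test_median_removes_isolated_spike(self):
        x = np.zeros(60)
        x[30] = 100.0
        assert imu.rolling_median(x, 10).max() < 1.0

    def test_median_matches_pandas_oracle_in_interior(self, rng):
        x = rng.normal(size=80)
        ours = imu.rolling_median(x, 9)
        oracle = (
            pd.Series(x).rolling(9, center=True, min_periods=9).median().to_numpy()
        )
        valid = ~np.isnan(oracle)
        np.testing.assert_allclose(ours[valid], oracle[valid])

    def test_moving_average_worked_example(self):
        np.testing.assert_allclose(
            imu.moving_average(np.array([0.0, 10.0, 0.0, 0.0]), 2),
            [0.0, 5.0, 5.0, 0.0],
        )

    def test_length_preserving_and_columnwise(self, rng):
        x = rng.normal(size=(150, 3))
        for fn in (imu.rolling_median, imu.moving_average):
            out = fn(x, 10)
            assert out.shape == x.shape

    def test_empty_series_raises(self):
        for fn in (imu.rolling_median, imu.moving_average):
            with pytest.raises(ValueError):
                fn(np.array([]), 10)

    def test_median_window_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            imu.rolling_median(np.zeros(5), 10)


class TestCleanRecording:
    def test_all_zero_recording_stays_zero(self, noiseless_profile):
        rec = sd.forward_model(sd.static_templates()[0], noiseless_profile)
        zero = rec.copy_with(
            flex=np.zeros_like(rec.flex),
            accel_body=np.zeros_like(rec.accel_body),
            accel_earth=np.zeros_like(rec.accel_earth),
            gyro=np.zeros_like(rec.gyro),
        )
        out = imu.clean_recording(zero)
        for name in ("flex", "accel_body", "accel_earth", "gyro"):
            np.testing.assert_allclose(getattr(out, name), 0.0)

    def test_matches_explicit_filter_chain(self, noiseless_profile):
        rec = sd.forward_model(sd.dynamic_templates()[0], noiseless_profile)
        out = imu.clean_recording(rec, ac_noise=True)
        expected = imu.moving_average(
            imu.moving_average(imu.rolling_median(rec.gyro, 10), 10), 10
        )
        np.testing.assert_allclose(out.gyro, expected)

    def test_smooth_signal_morphology_preserved(self, noiseless_profile):
        # a 10-sample average of a smooth signal deviates by at most
        # max|x''| * w^2 / 8 per sample (Taylor bound on a centered mean)
        rec = sd.forward_model(sd.dynamic_templates()[0], noiseless_profile)
        out = imu.clean_recording(rec)
        dt = 1.0 / rec.fs
        curv = np.abs(np.diff(rec.accel_earth, 2, axis=0)).max() / dt**2
        bound = 3 * curv * (10 * dt) ** 2 / 8  # three cascaded windows
        interior = slice(10, -10)
        assert (
            np.abs(out.accel_earth - rec.accel_earth)[interior].max() < bound
        )

    def test_quaternions_untouched(self, noiseless_profile):
        rec = sd.forward_model(sd.dynamic_templates()[1], noiseless_profile)
        out = imu.clean_recording(rec, ac_noise=True)
        np.testing.assert_array_equal(out.quat, rec.quat)


class TestNormalizer:
    def _rec(self, mat):
        from signglove.recording import GestureRecording

        return GestureRecording.from_matrix(mat, "s01", "g", "static")

    def test_two_point_channel_maps_to_unit_interval(self):
        mat = np.zeros((2, 18))
        mat[:, 0] = [2.0, 4.0]
        rec = self._rec(mat)
        state = imu.fit_normalizer([rec])
        with pytest.warns(UserWarning):  # the other channels are constant
            out = imu.apply_normalizer(state, rec)
        np.testing.assert_allclose(out.flex[:, 0], [0.0, 1.0])

    def test_fitted_data_lands_in_unit_interval(self, small_dynamic_dataset):
        recs = small_dynamic_dataset[:10]
        state = imu.fit_normalizer(recs)
        for rec in recs:
            mat = imu.apply_normalizer(state, rec).to_matrix()
            assert mat.min() >= -1e-12 and mat.max() <= 1 + 1e-12

    def test_unseen_value_above_max_exceeds_one(self):
        mat = np.zeros((2, 18))
        mat[:, 0] = [0.0, 1.0]
        state = imu.fit_normalizer([self._rec(mat)])
        probe = np.zeros((2, 18))
        probe[:, 0] = [0.0, 2.0]
        with pytest.warns(UserWarning):
            out = imu.apply_normalizer(state, self._rec(probe))
        assert out.flex[1, 0] > 1.0

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            imu.fit_normalizer([])

    def test_constant_channel_maps_to_zero_with_warning(self):
        mat = np.ones((3, 18))
        rec = self._rec(mat)
        state = imu.fit_normalizer([rec])
        with pytest.warns(UserWarning):
            out = imu.apply_normalizer(state, rec)
        np.testing.assert_allclose(out.to_matrix(), 0.0)
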