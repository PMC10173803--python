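"""Attitude filter, Euler conversion and rotation-matrix checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from qstm.orientation import (
    AhrsConfig,
    EulerAngles,
    ImuSample,
    MadgwickAhrs,
    Quaternion,
    ahrs_update,
    estimate_biases,
    euler_to_quat,
    quat_to_euler,
    rotation_matrix_zyx,
)


def _samples(gyro, accel, n=1):
    return [
        ImuSample(timestamp=i * 0.005, accel=np.asarray(accel), gyro=np.asarray(gyro))
        for i in range(n)
    ]


class TestBiasEstimation:
    def test_constant_gyro_bias_is_the_constant(self):
        gyro_bias, _ = estimate_biases(_samples((0.01, -0.02, 0.0), (0, 0, 1), n=100))
        assert np.allclose(gyro_bias, (0.01, -0.02, 0.0))

    def test_zero_mean_noise_averages_out(self, rng):
        sigma, n = 0.05, 1000
        samples = [
            ImuSample(i * 0.005, np.array([0, 0, 1.0]), rng.normal(0, sigma, 3))
            for i in range(n)
        ]
        gyro_bias, accel_bias = estimate_biases(samples)
        # direct-mean oracle: law of large numbers, 4 sigma / sqrt(n) bound
        assert np.all(np.abs(gyro_bias) < 4 * sigma / math.sqrt(n))
        assert np.allclose(accel_bias, 0.0)

    def test_gravity_pose_accel_bias_zero(self):
        _, accel_bias = estimate_biases(_samples((0, 0, 0), (0, 0, 1), n=10))
        assert np.allclose(accel_bias, 0.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no calibration samples"):
            estimate_biases([])


class TestAhrsUpdate:
    def test_gravity_aligned_rest_is_fixed_point(self):
        filt = MadgwickAhrs(AhrsConfig())
        q = filt.update((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        assert np.allclose(q.as_array(), [1, 0, 0, 0], atol=1e-12)

    def test_constant_yaw_rate_integrates_to_omega_t(self):
        # rotation about the gravity axis: accel carries no yaw information,
        # so the estimate must follow pure gyro integration
        omega, t_total = 1.0, 2.0
        cfg = AhrsConfig(update_rate=200.0)
        filt = MadgwickAhrs(cfg)
        for _ in range(int(t_total * cfg.update_rate)):
            filt.update((0.0, 0.0, omega), (0.0, 0.0, 1.0))
        expected = math.degrees(omega * t_total)
        assert filt.euler.yaw == pytest.approx(expected, abs=1.0)

    def test_zero_accel_skips_correction(self):
        cfg = AhrsConfig(update_rate=200.0)
        a = MadgwickAhrs(cfg)
        b = MadgwickAhrs(cfg)
        for _ in range(50):
            a.update((0.3, -0.2, 0.1), (0.0, 0.0, 0.0))
        # independent pure-gyro integration oracle
        q = np.array([1.0, 0, 0, 0])
        for _ in range(50):
            w = np.array([0.3, -0.2, 0.1])
            q0, q1, q2, q3 = q
            dq = 0.5 * np.array(
                [
                    -q1 * w[0] - q2 * w[1] - q3 * w[2],
                    q0 * w[0] + q2 * w[2] - q3 * w[1],
                    q0 * w[1] - q1 * w[2] + q3 * w[0],
                    q0 * w[2] + q1 * w[1] - q2 * w[0],
                ]
            )
            q = q + dq * cfg.dt
            q /= np.linalg.norm(q)
        assert np.allclose(a.quaternion.as_array(), q, atol=1e-12)
        del b

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_norm_conserved_under_random_updates(self, seed):
        rng = np.random.default_rng(seed)
        filt = MadgwickAhrs(AhrsConfig())
        for _ in range(200):
            q = filt.update(rng.uniform(-10, 10, 3), rng.normal(0, 1, 3))
            assert abs(q.norm - 1.0) < 1e-9

    def test_functional_wrapper_matches_class(self):
        cfg = AhrsConfig()
        sample = ImuSample(0.0, np.array([0.1, 0.0, 0.95]), np.array([0.2, -0.1, 0.05]))
        filt = MadgwickAhrs(cfg)
        expected = filt.update(sample.gyro, sample.accel)
        got = ahrs_update(Quaternion.identity(), sample, cfg)
        assert np.allclose(got.as_array(), expected.as_array())

    def test_initialize_from_accel_recovers_tilt(self, rng):
        for _ in range(20):
            q_true = rng.normal(size=4)
            q_true /= np.linalg.norm(q_true)
            r = Rotation.from_quat([q_true[1], q_true[2], q_true[3], q_true[0]])
            accel = r.apply([0, 0, 1], inverse=True)
            filt = MadgwickAhrs()
            q = filt.initialize_from_accel(accel)
            predicted = q.rotation_matrix().T @ np.array([0, 0, 1.0])
            assert np.allclose(predicted, accel, atol=1e-9)

    def test_yaw_returns_after_excursion_and_return(self):
        # two full periods of a multi-axis sinusoidal sweep end at the
        # starting attitude; clean input must not leave residual yaw drift
        from qstm.simulator import SinusoidalSweep, _body_rates

        fs, duration = 200.0, 4.0
        profile = SinusoidalSweep(amplitude=(20.0, 15.0, 25.0), freq_hz=0.5)
        n = int(duration * fs)
        t = np.arange(1, n + 1) / fs
        t_mid = t - 0.5 / fs
        gyro = _body_rates(profile.euler_deg(t_mid), profile.euler_rate_deg(t_mid))
        euler = profile.euler_deg(t)
        rot = Rotation.from_euler("ZYX", euler, degrees=True).as_matrix()
        accel = rot[:, 2, :]
        filt = MadgwickAhrs(AhrsConfig(update_rate=fs))
        for i in range(n):
            filt.update(gyro[i], accel[i])
        assert abs(filt.euler.yaw) < 2.0

    def test_steady_sinusoid_tracking_error_small(self):
        # single-axis roll sinusoid with consistent inertial streams: the
        # tracked angle must stay within a few percent of the amplitude
        fs, f, amp = 200.0, 2.0, math.radians(30)
        n = int(8 * fs)
        t = np.arange(1, n + 1) / fs
        roll = amp * np.sin(2 * np.pi * f * t)
        t_mid = t - 0.5 / fs
        gyro_x = amp * 2 * np.pi * f * np.cos(2 * np.pi * f * t_mid)
        filt = MadgwickAhrs(AhrsConfig(update_rate=fs))
        errs = []
        for i in range(n):
            filt.update((gyro_x[i], 0, 0), (0, math.sin(roll[i]), math.cos(roll[i])))
            if t[i] > 2.0:
                errs.append(abs(filt.euler.roll - math.degrees(roll[i])))
        assert max(errs) < 0.0215 * math.degrees(amp)


class TestEulerConversion:
    def test_identity_maps_to_zero_angles(self):
        e = quat_to_euler(Quaternion.identity())
        assert (e.yaw, e.pitch, e.roll) == (0.0, 0.0, 0.0)

    def test_pure_z_rotation_is_yaw(self):
        c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
        e = quat_to_euler(Quaternion(c, 0.0, 0.0, s))
        assert e.yaw == pytest.approx(90.0)
        assert e.pitch == pytest.approx(0.0)
        assert e.roll == pytest.approx(0.0)

    def test_roundtrip_matches_quaternion_rotation(self, rng):
        # independent oracle: the rotation matrix recomposed from the Euler
        # angles must reproduce the quaternion's own rotation matrix
        for _ in range(50):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            quat = Quaternion.from_array(q)
            e = quat_to_euler(quat)
            if abs(e.pitch) > 89.0:
                continue
            assert np.allclose(
                rotation_matrix_zyx(e), quat.rotation_matrix(), atol=1e-9
            )

    def test_angle_ranges(self, rng):
        for _ in range(100):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            e = quat_to_euler(Quaternion.from_array(q))
            assert -180.0 <= e.yaw <= 180.0
            assert -90.0 <= e.pitch <= 90.0
            assert -180.0 <= e.roll <= 180.0

    def test_gimbal_adjacent_quaternion_is_clamped(self):
        # pitch argument a rounding error beyond |1| must not raise
        q = euler_to_quat(EulerAngles(0.0, 90.0, 0.0))
        e = quat_to_euler(q)
        assert e.pitch == pytest.approx(90.0, abs=1e-6)


class TestRotationMatrix:
    def test_zero_angles_give_identity(self):
        assert np.allclose(rotation_matrix_zyx(EulerAngles(0, 0, 0)), np.eye(3))

    def test_pure_yaw_maps_x_to_y(self):
        r = rotation_matrix_zyx(EulerAngles(90.0, 0.0, 0.0))
        assert np.allclose(r @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_orthonormal_with_unit_determinant(self, rng):
        for _ in range(25):
            e = EulerAngles(*rng.uniform(-180, 180, 3) * [1, 0.49, 1])
            r = rotation_matrix_zyx(e)
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_intrinsic_zyx(self, rng):
        for _ in range(25):
            angles = rng.uniform(-90, 90, 3)
            e = EulerAngles(*angles)
            expected = Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()
            assert np.allclose(rotation_matrix_zyx(e), expected, atol=1e-12)
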