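"""Attitude estimation for the handheld device from 6-DOF inertial data.

The device carries a 3-axis accelerometer and a 3-axis gyroscope.  Their
streams are fused at 200 Hz into a unit quaternion by a gradient-descent
attitude filter (IMU-only variant, no magnetometer): gyroscope rates are
integrated to propagate the attitude while the accelerometer's gravity
observation supplies a corrective gradient step of magnitude ``beta``
(rad/s) that bounds tilt drift.  Heading (yaw) is observable only through
gyro integration, which is sufficient here because the downstream gravity
correction of the force stream depends on tilt alone.

Conventions
-----------
* Quaternions are scalar-first ``(q0, q1, q2, q3)`` and always unit norm.
* ``q`` rotates device-frame vectors into the global (gravity) frame; the
  global +Z axis points opposite gravity and the device rests in its
  calibration cradle at identity attitude.
* Accelerometer samples are specific force in g; only their direction is
  used by the filter.  Gyroscope samples are body rates in rad/s.
* Euler angles are intrinsic Z-Y-X (yaw ψ, pitch θ, roll ∅), in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Quaternion",
    "EulerAngles",
    "ImuSample",
    "AhrsConfig",
    "MadgwickAhrs",
    "estimate_biases",
    "ahrs_update",
    "quat_to_euler",
    "euler_to_quat",
    "rotation_matrix_zyx",
]


@dataclass(frozen=True)
class Quaternion:
    """Unit attitude quaternion, scalar part first."""

    q0: float
    q1: float
    q2: float
    q3: float

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, q: Sequence[float]) -> "Quaternion":
        return cls(float(q[0]), float(q[1]), float(q[2]), float(q[3]))

    def as_array(self) -> np.ndarray:
        return np.array([self.q0, self.q1, self.q2, self.q3], dtype=float)

    @property
    def norm(self) -> float:
        return math.sqrt(self.q0**2 + self.q1**2 + self.q2**2 + self.q3**2)

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize a zero quaternion")
        return Quaternion(self.q0 / n, self.q1 / n, self.q2 / n, self.q3 / n)

    def conjugate(self) -> "Quaternion":
        return Quaternion(self.q0, -self.q1, -self.q2, -self.q3)

    def rotation_matrix(self) -> np.ndarray:
        """3x3 matrix mapping device-frame vectors to the global frame."""
        q0, q1, q2, q3 = self.q0, self.q1, self.q2, self.q3
        return np.array(
            [
                [
                    q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                    2.0 * (q1 * q2 - q0 * q3),
                    2.0 * (q1 * q3 + q0 * q2),
                ],
                [
                    2.0 * (q1 * q2 + q0 * q3),
                    q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                    2.0 * (q2 * q3 - q0 * q1),
                ],
                [
                    2.0 * (q1 * q3 - q0 * q2),
                    2.0 * (q2 * q3 + q0 * q1),
                    q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
                ],
            ]
        )

    def rotate(self, v: Sequence[float]) -> np.ndarray:
        """Rotate a device-frame vector into the global frame."""
        return self.rotation_matrix() @ np.asarray(v, dtype=float)


@dataclass(frozen=True)
class EulerAngles:
    """Yaw/pitch/roll in degrees (intrinsic Z-Y-X sequence).

    yaw and roll lie in [-180, 180], pitch in [-90, 90].
    """

    yaw: float
    pitch: float
    roll: float

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll], dtype=float)


@dataclass
class ImuSample:
    """One inertial frame: accel in g, gyro in rad/s."""

    timestamp: float
    accel: np.ndarray
    gyro: np.ndarray
    bias_removed: bool = False

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)


@dataclass
class AhrsConfig:
    """Gradient-descent filter settings.

    ``beta`` is the magnitude of the accelerometer corrective step in
    rad/s (unit gain by default); ``update_rate`` the fusion rate in Hz.
    """

    beta: float = 1.0
    update_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.update_rate <= 0:
            raise ValueError("update_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.update_rate


def estimate_biases(
    samples: Sequence[ImuSample],
    expected_gravity: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate sensor bias offsets from samples taken at rest.

    The gyro bias is the per-axis mean rate.  The accel bias is the mean
    deviation of the accelerometer from the gravity vector expected in the
    calibration pose (device flat in its cradle: ``(0, 0, 1)`` g).

    Raises ``ValueError`` on empty input.
    """
    if len(samples) == 0:
        raise ValueError("no calibration samples")
    gyro = np.stack([s.gyro for s in samples])
    accel = np.stack([s.accel for s in samples])
    gyro_bias = gyro.mean(axis=0)
    accel_bias = accel.mean(axis=0) - np.asarray(expected_gravity, dtype=float)
    return gyro_bias, accel_bias


class MadgwickAhrs:
    """Gradient-descent IMU attitude filter (modified form).

    Each :meth:`update` first propagates the quaternion through the gyro
    rates, then applies a corrective step of ``beta`` times the raw
    gradient of the accelerometer-gravity alignment error evaluated at
    the propagated attitude, and renormalises.  Two departures from the
    classical normalised-gradient formulation: the gradient is used
    unnormalised, so the correction is proportional to the misalignment
    and vanishes at convergence (the fixed-magnitude normalised step
    limit-cycles at ±2βΔt rad under a unit gain); and it is evaluated
    after gyro propagation, which removes a one-sample lag that grows
    with motion frequency.  For a small misalignment ε the gradient
    magnitude is ≈ 2ε, giving a tilt-correction time constant of
    1/(2β) s.  A zero-norm accelerometer sample disables the corrective
    step for that update and the attitude propagates on the gyro alone.
    """

    def __init__(
        self,
        config: AhrsConfig | None = None,
        initial: Quaternion | None = None,
    ) -> None:
        self.config = config or AhrsConfig()
        q = initial or Quaternion.identity()
        self._q0, self._q1, self._q2, self._q3 = q.normalized().as_array()

    @property
    def quaternion(self) -> Quaternion:
        return Quaternion(self._q0, self._q1, self._q2, self._q3)

    @property
    def euler(self) -> EulerAngles:
        return quat_to_euler(self.quaternion)

    def initialize_from_accel(self, accel: Sequence[float]) -> Quaternion:
        """Set a tilt-only initial attitude from a static accel sample.

        Chooses the minimal rotation aligning the measured specific-force
        direction with global +Z; yaw is left at zero (unobservable).
        """
        a = np.asarray(accel, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("zero accelerometer vector")
        a = a / n
        z = np.array([0.0, 0.0, 1.0])
        # rotation taking body-frame a onto +Z (global gravity direction)
        axis = np.cross(a, z)
        s = np.linalg.norm(axis)
        c = float(np.dot(a, z))
        if s < 1e-12:
            q = Quaternion.identity() if c > 0 else Quaternion(0.0, 1.0, 0.0, 0.0)
        else:
            angle = math.atan2(s, c)
            axis = axis / s
            half = 0.5 * angle
            sh = math.sin(half)
            q = Quaternion(math.cos(half), axis[0] * sh, axis[1] * sh, axis[2] * sh)
        self._q0, self._q1, self._q2, self._q3 = q.as_array()
        return q

    def update(
        self,
        gyro: Sequence[float],
        accel: Sequence[float],
        dt: float | None = None,
    ) -> Quaternion:
        """Advance the attitude by one fusion step and return it.

        ``dt`` defaults to the configured update interval; callers feeding a
        decimated multi-rate stream may pass the actual covered interval.
        """
        if dt is None:
            dt = self.config.dt
        gx, gy, gz = float(gyro[0]), float(gyro[1]), float(gyro[2])
        ax, ay, az = float(accel[0]), float(accel[1]), float(accel[2])
        q0, q1, q2, q3 = self._q0, self._q1, self._q2, self._q3

        # predict: integrate 0.5 * q ⊗ (0, ω) over dt
        p0 = q0 + 0.5 * (-q1 * gx - q2 * gy - q3 * gz) * dt
        p1 = q1 + 0.5 * (q0 * gx + q2 * gz - q3 * gy) * dt
        p2 = q2 + 0.5 * (q0 * gy - q1 * gz + q3 * gx) * dt
        p3 = q3 + 0.5 * (q0 * gz + q1 * gy - q2 * gx) * dt

        a_norm = math.sqrt(ax * ax + ay * ay + az * az)
        if a_norm > 0.0:
            ax, ay, az = ax / a_norm, ay / a_norm, az / a_norm

            _2p0, _2p1, _2p2, _2p3 = 2 * p0, 2 * p1, 2 * p2, 2 * p3
            _4p0, _4p1, _4p2 = 4 * p0, 4 * p1, 4 * p2
            _8p1, _8p2 = 8 * p1, 8 * p2
            p0p0, p1p1, p2p2, p3p3 = p0 * p0, p1 * p1, p2 * p2, p3 * p3

            # gradient of the gravity-alignment objective at the predicted
            # attitude; applied proportionally (no unit normalisation)
            s0 = _4p0 * p2p2 + _2p2 * ax + _4p0 * p1p1 - _2p1 * ay
            s1 = (
                _4p1 * p3p3
                - _2p3 * ax
                + 4 * p0p0 * p1
                - _2p0 * ay
                - _4p1
                + _8p1 * p1p1
                + _8p1 * p2p2
                + _4p1 * az
            )
            s2 = (
                4 * p0p0 * p2
                + _2p0 * ax
                + _4p2 * p3p3
                - _2p3 * ay
                - _4p2
                + _8p2 * p1p1
                + _8p2 * p2p2
                + _4p2 * az
            )
            s3 = 4 * p1p1 * p3 - _2p1 * ax + 4 * p2p2 * p3 - _2p2 * ay
            beta = self.config.beta
            p0 -= beta * s0 * dt
            p1 -= beta * s1 * dt
            p2 -= beta * s2 * dt
            p3 -= beta * s3 * dt

        q0, q1, q2, q3 = p0, p1, p2, p3
        inv_norm = 1.0 / math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
        self._q0 = q0 * inv_norm
        self._q1 = q1 * inv_norm
        self._q2 = q2 * inv_norm
        self._q3 = q3 * inv_norm
        return self.quaternion


def ahrs_update(
    state: Quaternion, sample: ImuSample, config: AhrsConfig
) -> Quaternion:
    """Single functional fusion step (see :class:`MadgwickAhrs`)."""
    filt = MadgwickAhrs(config, initial=state)
    return filt.update(sample.gyro, sample.accel)


def quat_to_euler(q: Quaternion) -> EulerAngles:
    """Convert a unit quaternion to Z-Y-X Euler angles in degrees.

    The pitch argument is clamped to [-1, 1] before ``asin`` so that
    quaternions a rounding error past gimbal lock remain convertible.
    """
    q0, q1, q2, q3 = q.q0, q.q1, q.q2, q.q3
    yaw = math.degrees(
        math.atan2(2.0 * (q1 * q2 + q0 * q3), q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3)
    )
    sin_pitch = -2.0 * (q1 * q3 - q0 * q2)
    sin_pitch = max(-1.0, min(1.0, sin_pitch))
    pitch = math.degrees(math.asin(sin_pitch))
    roll = math.degrees(
        math.atan2(2.0 * (q0 * q1 + q2 * q3), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3)
    )
    return EulerAngles(yaw, pitch, roll)


def euler_to_quat(e: EulerAngles) -> Quaternion:
    """Inverse of :func:`quat_to_euler` (used by the simulator and tests)."""
    r = Rotation.from_euler("ZYX", [e.yaw, e.pitch, e.roll], degrees=True)
    x, y, z, w = r.as_quat()
    return Quaternion(w, x, y, z)


def rotation_matrix_zyx(e: EulerAngles) -> np.ndarray:
    """Rotation matrix R(ψ,θ,∅) = Rz(ψ) · Ry(θ) · Rx(∅).

    Maps device-frame vectors into the global frame; orthonormal with
    determinant +1.
    """
    cy, sy = math.cos(math.radians(e.yaw)), math.sin(math.radians(e.yaw))
    cp, sp = math.cos(math.radians(e.pitch)), math.sin(math.radians(e.pitch))
    cr, sr = math.cos(math.radians(e.roll)), math.sin(math.radians(e.roll))
    rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    return rz @ ry @ rx
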