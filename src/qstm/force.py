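"""Load-cell force calibration and gravity correction.

The treatment blade hangs from two 3-D load cells whose six voltage
channels are converted to Newtons through manufacturer characterization
matrices.  Because the blade (weight ``Mb`` ≈ 2.5 N) is suspended from the
sensors, its gravity load contaminates every orientation of the device;
the correction here rotates the measured force into the global frame with
the current attitude, subtracts the blade weight along global Z, and
rotates back, leaving only the externally applied force.

Processing chain per channel (firmware order):

1. subtract the no-load offset voltages measured during calibration;
2. rolling-mean filter (window ``n`` = 25 at the 500 Hz master rate);
3. characterization-matrix multiply, with a baseline-shift correction of
   ``ξ`` volts on the gravity-aligned z channel that restores the uniform
   distribution of the blade's weight in the device frame;
4. sum the two cells into one device-frame force vector;
5. gravity-correct using the fused attitude and take the Euclidean norm
   as the resultant (the instantaneous dose-load).

The measured calibration offsets include the blade-tension shift on z, so
step 3 adds the shift back; the rotating tension is then removed exactly
by the frame transformation of step 5 rather than by a constant baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .orientation import (
    AhrsConfig,
    EulerAngles,
    ImuSample,
    MadgwickAhrs,
    Quaternion,
    quat_to_euler,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationParams",
    "RawSample",
    "RawStream",
    "ForceState",
    "ForceStream",
    "compute_voltage_offsets",
    "rolling_mean_filter",
    "voltage_to_force",
    "combine_cells",
    "gravity_correct",
    "process_stream",
]


@dataclass
class CalibrationParams:
    """Device calibration constants and processing rates.

    ``a_left``/``a_right`` are the 3x3 voltage→force characterization
    matrices (N per volt).  ``v_zero_*`` are the electronics zeros of the
    six channels (volts, from the device configuration); ``v_off_*`` are
    the no-load offsets measured in the calibration cradle and therefore
    include the blade-tension shift ``xi`` on the z channel.
    """

    a_left: np.ndarray
    a_right: np.ndarray
    v_zero_left: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v_zero_right: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v_off_left: np.ndarray | None = None
    v_off_right: np.ndarray | None = None
    xi: float = 0.0
    blade_weight: float = 2.5
    window: int = 25
    master_rate: float = 500.0
    ahrs_rate: float = 200.0
    output_rate: float = 100.0
    saturation: float = 325.0

    def __post_init__(self) -> None:
        self.a_left = np.asarray(self.a_left, dtype=float)
        self.a_right = np.asarray(self.a_right, dtype=float)
        for name, a in (("a_left", self.a_left), ("a_right", self.a_right)):
            if a.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
            if abs(np.linalg.det(a)) < 1e-9:
                raise ValueError(f"{name} is not invertible")
        self.v_zero_left = np.asarray(self.v_zero_left, dtype=float)
        self.v_zero_right = np.asarray(self.v_zero_right, dtype=float)
        if self.v_off_left is not None:
            self.v_off_left = np.asarray(self.v_off_left, dtype=float)
        if self.v_off_right is not None:
            self.v_off_right = np.asarray(self.v_off_right, dtype=float)
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.blade_weight <= 0:
            raise ValueError("blade_weight must be positive")
        for r in (self.master_rate, self.ahrs_rate, self.output_rate):
            if r <= 0:
                raise ValueError("rates must be positive")

    def to_dict(self) -> dict:
        d = {
            "a_left": self.a_left.tolist(),
            "a_right": self.a_right.tolist(),
            "v_zero_left": self.v_zero_left.tolist(),
            "v_zero_right": self.v_zero_right.tolist(),
            "xi": float(self.xi),
            "blade_weight": float(self.blade_weight),
            "window": int(self.window),
            "rates": {
                "master": float(self.master_rate),
                "ahrs": float(self.ahrs_rate),
                "output": float(self.output_rate),
            },
            "saturation": float(self.saturation),
        }
        if self.v_off_left is not None:
            d["v_off_left"] = self.v_off_left.tolist()
        if self.v_off_right is not None:
            d["v_off_right"] = self.v_off_right.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        rates = d.get("rates", {})
        return cls(
            a_left=np.asarray(d["a_left"], dtype=float),
            a_right=np.asarray(d["a_right"], dtype=float),
            v_zero_left=np.asarray(d.get("v_zero_left", np.zeros(3)), dtype=float),
            v_zero_right=np.asarray(d.get("v_zero_right", np.zeros(3)), dtype=float),
            v_off_left=(
                np.asarray(d["v_off_left"], dtype=float) if "v_off_left" in d else None
            ),
            v_off_right=(
                np.asarray(d["v_off_right"], dtype=float)
                if "v_off_right" in d
                else None
            ),
            xi=float(d.get("xi", 0.0)),
            blade_weight=float(d.get("blade_weight", 2.5)),
            window=int(d.get("window", 25)),
            master_rate=float(rates.get("master", 500.0)),
            ahrs_rate=float(rates.get("ahrs", 200.0)),
            output_rate=float(rates.get("output", 100.0)),
            saturation=float(d.get("saturation", 325.0)),
        )


@dataclass
class RawSample:
    """One timestamped device frame: two load-cell voltage triples plus IMU."""

    timestamp: float
    v_left: np.ndarray
    v_right: np.ndarray
    imu: ImuSample
    button: bool = False


@dataclass
class RawStream:
    """Column-oriented raw sample stream at the 500 Hz master rate."""

    timestamp: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    button: np.ndarray
    rate: float = 500.0

    def __post_init__(self) -> None:
        self.timestamp = np.asarray(self.timestamp, dtype=float)
        self.v_left = np.asarray(self.v_left, dtype=float)
        self.v_right = np.asarray(self.v_right, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.button = np.asarray(self.button, dtype=bool)
        n = len(self.timestamp)
        for name in ("v_left", "v_right", "accel", "gyro"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape (n, 3)")
        if self.button.shape != (n,):
            raise ValueError("button must have shape (n,)")
        if n > 1 and np.any(np.diff(self.timestamp) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamp)

    def __getitem__(self, i: int) -> RawSample:
        return RawSample(
            timestamp=float(self.timestamp[i]),
            v_left=self.v_left[i],
            v_right=self.v_right[i],
            imu=ImuSample(
                timestamp=float(self.timestamp[i]),
                accel=self.accel[i],
                gyro=self.gyro[i],
            ),
            button=bool(self.button[i]),
        )

    def slice(self, lo: int, hi: int) -> "RawStream":
        return RawStream(
            timestamp=self.timestamp[lo:hi],
            v_left=self.v_left[lo:hi],
            v_right=self.v_right[lo:hi],
            accel=self.accel[lo:hi],
            gyro=self.gyro[lo:hi],
            button=self.button[lo:hi],
            rate=self.rate,
        )


@dataclass(frozen=True)
class ForceState:
    """Calibrated force at one output tick."""

    timestamp: float
    f_local: np.ndarray
    f_corrected: np.ndarray
    f_rms: float
    attitude: Quaternion
    euler: EulerAngles
    button: bool = False


@dataclass
class ForceStream:
    """Column-oriented calibrated force stream at the 100 Hz output rate.

    ``f_local`` is the summed device-frame force (blade tension included),
    ``f_corrected`` the gravity-corrected force, ``f_rms`` its norm (the
    instantaneous dose-load).
    """

    timestamp: np.ndarray
    f_local: np.ndarray
    f_corrected: np.ndarray
    f_rms: np.ndarray
    quat: np.ndarray
    euler: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    button: np.ndarray
    rate: float = 100.0

    def __len__(self) -> int:
        return len(self.timestamp)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def __getitem__(self, i: int) -> ForceState:
        return ForceState(
            timestamp=float(self.timestamp[i]),
            f_local=self.f_local[i],
            f_corrected=self.f_corrected[i],
            f_rms=float(self.f_rms[i]),
            attitude=Quaternion.from_array(self.quat[i]),
            euler=EulerAngles(*self.euler[i]),
            button=bool(self.button[i]),
        )


def compute_voltage_offsets(
    v_left: np.ndarray,
    v_right: np.ndarray,
    v_zero_left: Sequence[float] = (0.0, 0.0, 0.0),
    v_zero_right: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """No-load offset voltages and blade-tension shift from calibration data.

    The offsets are the per-channel means over the calibration window
    (device untouched in its cradle).  ``xi`` is the residual baseline
    shift on the gravity-aligned z channel attributable to the suspended
    blade: the calibration-pose z mean minus the electronics zero,
    averaged over the two cells (shared-ξ model).
    """
    v_left = np.atleast_2d(np.asarray(v_left, dtype=float))
    v_right = np.atleast_2d(np.asarray(v_right, dtype=float))
    if v_left.size == 0 or v_right.size == 0:
        raise ValueError("no calibration samples")
    off_left = v_left.mean(axis=0)
    off_right = v_right.mean(axis=0)
    shift_left = off_left[2] - float(v_zero_left[2])
    shift_right = off_right[2] - float(v_zero_right[2])
    xi = 0.5 * (shift_left + shift_right)
    return off_left, off_right, xi


def rolling_mean_filter(
    voltages: np.ndarray, offsets: Sequence[float], n: int
) -> np.ndarray:
    """Causal rolling mean of the offset-subtracted voltage stream.

    Output ``t`` is the mean of the last ``n`` offset-subtracted samples;
    during warm-up (fewer than ``n`` samples seen) the mean of the
    available samples is used, avoiding a startup transient.
    """
    if n < 1:
        raise ValueError("window must be >= 1")
    v = np.atleast_2d(np.asarray(voltages, dtype=float)) - np.asarray(
        offsets, dtype=float
    )
    c = np.concatenate([np.zeros((1, v.shape[1])), np.cumsum(v, axis=0)])
    hi = np.arange(1, len(v) + 1)
    lo = np.maximum(0, hi - n)
    return (c[hi] - c[lo]) / (hi - lo)[:, None]


def voltage_to_force(
    vf: np.ndarray, a: np.ndarray, xi: float = 0.0
) -> np.ndarray:
    """Characterization-matrix conversion of filtered voltages to Newtons.

    ``F = A · VF`` with the z component reduced by ``A33 · ξ`` (the
    baseline-shift correction on the gravity-aligned channel).  Accepts a
    single 3-vector or an ``(n, 3)`` stream.
    """
    a = np.asarray(a, dtype=float)
    vf = np.asarray(vf, dtype=float)
    f = vf @ a.T
    correction = a[2, 2] * xi
    if f.ndim == 1:
        f = f.copy()
        f[2] -= correction
    else:
        f[:, 2] -= correction
    return f


def combine_cells(f_left: np.ndarray, f_right: np.ndarray) -> np.ndarray:
    """Componentwise sum of the two load cells into one device-frame force."""
    return np.asarray(f_left, dtype=float) + np.asarray(f_right, dtype=float)


def _quat_to_scipy(quat: np.ndarray) -> Rotation:
    q = np.atleast_2d(np.asarray(quat, dtype=float))
    return Rotation.from_quat(np.column_stack([q[:, 1], q[:, 2], q[:, 3], q[:, 0]]))


def gravity_correct(
    f3d: np.ndarray,
    attitude: Quaternion | np.ndarray,
    blade_weight: float,
) -> tuple[np.ndarray, float | np.ndarray]:
    """Remove the suspended blade's gravity load from a device-frame force.

    Rotates ``f3d`` into the global frame with the attitude, subtracts
    ``(0, 0, Mb)``, rotates back with the transposed matrix, and returns
    the corrected vector together with its Euclidean norm (the resultant
    dose-load).  Accepts single vectors or ``(n, 3)`` / ``(n, 4)`` arrays.
    """
    single = np.asarray(f3d).ndim == 1
    f = np.atleast_2d(np.asarray(f3d, dtype=float))
    if isinstance(attitude, Quaternion):
        quat = attitude.as_array()[None, :]
    else:
        quat = np.atleast_2d(np.asarray(attitude, dtype=float))
    rot = _quat_to_scipy(quat)
    f_inertial = rot.apply(f)
    f_inertial[:, 2] -= blade_weight
    f_corrected = rot.apply(f_inertial, inverse=True)
    f_rms = np.linalg.norm(f_corrected, axis=1)
    if single:
        return f_corrected[0], float(f_rms[0])
    return f_corrected, f_rms


def _ahrs_boundaries(n_master: int, master_rate: float, ahrs_rate: float) -> np.ndarray:
    """Master-sample indices at which the fusion filter consumes its input.

    The filter runs on its own uniform clock; each update consumes the
    master samples accumulated since the previous one (counts alternate
    2/3 for 500→200 Hz), so no interpolation is needed.
    """
    ratio = master_rate / ahrs_rate
    n_updates = int(np.floor(n_master / ratio))
    return np.round(np.arange(1, n_updates + 1) * ratio).astype(int)


def process_stream(
    stream: RawStream,
    cal: CalibrationParams,
    ahrs: AhrsConfig | None = None,
    gyro_bias: Sequence[float] | None = None,
    initial: Quaternion | None = None,
) -> ForceStream:
    """Run the full voltage→force→gravity-correction chain over a stream.

    The load-cell channels are processed at the master rate, attitude
    fusion consumes the stream at the (lower) fusion rate, and the result
    is decimated to the output rate.  Requires measured offsets and ξ in
    ``cal`` (see :func:`compute_voltage_offsets`).  Rows containing NaN
    voltages are replaced by the previous valid row with a logged warning.
    """
    if ahrs is None:
        ahrs = AhrsConfig(update_rate=cal.ahrs_rate)
    if cal.v_off_left is None or cal.v_off_right is None:
        raise ValueError("calibration offsets missing; run calibration first")

    v_left = stream.v_left.copy()
    v_right = stream.v_right.copy()
    bad = np.any(np.isnan(v_left), axis=1) | np.any(np.isnan(v_right), axis=1)
    if bad.any():
        logger.warning("%d samples with NaN voltages held at previous value", bad.sum())
        for arr in (v_left, v_right):
            for i in np.flatnonzero(bad):
                arr[i] = arr[i - 1] if i > 0 else 0.0

    vf_left = rolling_mean_filter(v_left, cal.v_off_left, cal.window)
    vf_right = rolling_mean_filter(v_right, cal.v_off_right, cal.window)
    # the measured offsets removed the blade-tension baseline together with
    # the electronics zero; restore the tension on z (negated ξ correction)
    # so the frame transformation below can remove it at every orientation.
    f_left = voltage_to_force(vf_left, cal.a_left, -cal.xi)
    f_right = voltage_to_force(vf_right, cal.a_right, -cal.xi)
    f3d = combine_cells(f_left, f_right)
    np.clip(f3d, -cal.saturation, cal.saturation, out=f3d)

    # attitude fusion on the decimated inertial stream
    n = len(stream)
    gyro = stream.gyro
    if gyro_bias is not None:
        gyro = gyro - np.asarray(gyro_bias, dtype=float)
    filt = MadgwickAhrs(ahrs, initial=initial)
    quat = np.empty((n, 4))
    boundaries = _ahrs_boundaries(n, cal.master_rate, cal.ahrs_rate)
    prev = 0
    current = filt.quaternion.as_array()
    for b in boundaries:
        g = gyro[prev:b].mean(axis=0)
        a = stream.accel[b - 1]
        dt = (b - prev) / cal.master_rate
        current = filt.update(g, a, dt=dt).as_array()
        quat[prev:b] = current
        prev = b
    quat[prev:] = current

    step = int(round(cal.master_rate / cal.output_rate))
    out = np.arange(0, n, step)
    f_local = f3d[out]
    quat_out = quat[out]
    f_corrected, f_rms = gravity_correct(f_local, quat_out, cal.blade_weight)
    rot = _quat_to_scipy(quat_out)
    euler = rot.as_euler("ZYX", degrees=True)  # yaw, pitch, roll

    return ForceStream(
        timestamp=stream.timestamp[out],
        f_local=f_local,
        f_corrected=f_corrected,
        f_rms=f_rms,
        quat=quat_out,
        euler=euler,
        accel=stream.accel[out],
        gyro=gyro[out],
        button=stream.button[out],
        rate=cal.output_rate,
    )
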