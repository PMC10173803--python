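"""Synthetic device-stream generator with full ground truth.

Stands in for the physical instrument: scripted treatment sessions are
turned into raw 500 Hz sample streams (dual load-cell voltages, IMU,
control button) by running the force model *backwards* — the scripted
applied force plus the blade's rotating gravity load is split across the
two cells, pushed through the inverted characterization matrices, and
offset, noise-corrupted and ADC-quantized into channel voltages.  The
IMU streams are generated analytically from the orientation profile
(gyro samples are interval-centred body rates, as a rate-integrating
MEMS gyro reports), so integrating them recovers the profile.

Stroke resultants are half-sine force-motion cycles riding on a contact
baseline; optional Gaussian "tissue-irregularity" bumps near the stroke
crests reproduce the redundant-peak shoulders seen on uneven body
contours, and a low-amplitude sinusoidal ripple models hand vibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .force import CalibrationParams, RawStream
from .orientation import EulerAngles, rotation_matrix_zyx

__all__ = [
    "StrokeScript",
    "SessionScript",
    "GroundTruth",
    "OrientationProfile",
    "StaticOrientation",
    "SinusoidalSweep",
    "default_calibration",
    "true_offsets",
    "make_noise",
    "simulate_session",
    "simulate_static_orientation",
]

PATTERNS = ("linear_cross_fiber", "fanning_curvilinear", "scanning", "sweeping")


def default_calibration() -> CalibrationParams:
    """Plausible characterization constants for the simulated device.

    Near-diagonal matrices with ~5 % cross-talk; the diagonal gains put
    one 0.025 mV ADC step at ~0.1-0.2 N on the compressive channel and
    ~0.05-0.1 N on the planar channels.
    """
    a_left = np.array(
        [
            [2000.0, 95.0, 80.0],
            [-90.0, 2100.0, 110.0],
            [100.0, -120.0, 4000.0],
        ]
    )
    a_right = np.array(
        [
            [2050.0, -85.0, 90.0],
            [105.0, 1950.0, -95.0],
            [-110.0, 130.0, 4100.0],
        ]
    )
    return CalibrationParams(
        a_left=a_left,
        a_right=a_right,
        v_zero_left=np.array([1.5e-3, -2.3e-3, 3.1e-3]),
        v_zero_right=np.array([-1.1e-3, 2.7e-3, -1.9e-3]),
    )


class OrientationProfile:
    """Identity orientation; base class for scripted attitude trajectories."""

    def euler_deg(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.zeros((t.size, 3))

    def euler_rate_deg(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.zeros((t.size, 3))


@dataclass
class StaticOrientation(OrientationProfile):
    """Smooth ramp from the calibration pose to a fixed attitude."""

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    ramp_time: float = 1.0

    def _s(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.clip(np.asarray(t, dtype=float) / self.ramp_time, 0.0, 1.0)
        s = 3 * x**2 - 2 * x**3  # smoothstep
        ds = np.where((t > 0) & (t < self.ramp_time), (6 * x - 6 * x**2) / self.ramp_time, 0.0)
        return s, ds

    def euler_deg(self, t: np.ndarray) -> np.ndarray:
        s, _ = self._s(t)
        return np.outer(s, [self.yaw, self.pitch, self.roll])

    def euler_rate_deg(self, t: np.ndarray) -> np.ndarray:
        _, ds = self._s(t)
        return np.outer(ds, [self.yaw, self.pitch, self.roll])


@dataclass
class SinusoidalSweep(OrientationProfile):
    """Sinusoidal attitude sweep, per-axis amplitudes in degrees."""

    amplitude: tuple[float, float, float] = (0.0, 0.0, 30.0)  # yaw, pitch, roll
    freq_hz: float = 0.25

    def euler_deg(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.outer(np.sin(2 * np.pi * self.freq_hz * t), self.amplitude)

    def euler_rate_deg(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = 2 * np.pi * self.freq_hz
        return np.outer(w * np.cos(w * t), self.amplitude)


def _body_rates(euler_deg: np.ndarray, euler_rate_deg: np.ndarray) -> np.ndarray:
    """Body angular rates (rad/s) from Z-Y-X Euler angles and their rates."""
    e = np.radians(np.atleast_2d(euler_deg))
    de = np.radians(np.atleast_2d(euler_rate_deg))
    dpsi, dtheta, dphi = de[:, 0], de[:, 1], de[:, 2]
    theta, phi = e[:, 1], e[:, 2]
    wx = dphi - dpsi * np.sin(theta)
    wy = dtheta * np.cos(phi) + dpsi * np.cos(theta) * np.sin(phi)
    wz = dpsi * np.cos(theta) * np.cos(phi) - dtheta * np.sin(phi)
    return np.column_stack([wx, wy, wz])


def _rotations(euler_deg: np.ndarray) -> np.ndarray:
    """Stack of device→global rotation matrices for an Euler trajectory."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("ZYX", np.atleast_2d(euler_deg), degrees=True).as_matrix()


@dataclass
class StrokeScript:
    """One burst of scripted strokes.

    ``peak_force`` is the true resultant crest of each cycle (before
    jitter), ``rate`` the stroke frequency; the resultant rides on
    ``baseline_force`` so the blade keeps skin contact between strokes.
    ``ripple_amplitude`` adds a Gaussian tissue-irregularity bump on each
    stroke's falling flank (a redundant-peak generator);
    ``vibration_amplitude`` adds sinusoidal hand-vibration ripple.
    """

    pattern: str = "linear_cross_fiber"
    peak_force: float = 25.0
    rate: float = 1.0
    n_strokes: int = 10
    baseline_force: float = 2.5
    planar_angle: float = 35.0
    ripple_amplitude: float = 0.0
    vibration_amplitude: float = 0.0
    vibration_freq: float = 9.0
    peak_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not 0 < self.rate <= 5.0:
            raise ValueError("stroke rate must lie in (0, 5] Hz")
        if not 0 < self.peak_force <= 325.0:
            raise ValueError("peak force must lie in (0, 325] N")
        if self.n_strokes < 1:
            raise ValueError("need at least one stroke")


@dataclass
class SessionScript:
    """A full scripted treatment session.

    ``subsessions`` is a list of sub-sessions, each a list of
    :class:`StrokeScript` bursts separated by ``burst_gap`` seconds of
    baseline contact; sub-sessions are separated by button-paused
    intervals of ``pause_duration`` seconds.
    """

    subsessions: list[list[StrokeScript]]
    pause_duration: float = 3.0
    calibration_duration: float = 1.5
    lead_time: float = 0.4
    burst_gap: float = 0.8
    orientation: OrientationProfile = field(default_factory=OrientationProfile)
    noise_v: float = 2.5e-5
    adc_resolution: float = 2.5e-5
    accel_noise: float = 2e-3
    gyro_noise: float = 2e-3
    seed: int = 0
    cal: CalibrationParams = field(default_factory=default_calibration)
    split: float = 0.5

    def __post_init__(self) -> None:
        if not self.subsessions or any(len(s) == 0 for s in self.subsessions):
            raise ValueError("every sub-session needs at least one stroke script")
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.noise_v < 0 or self.adc_resolution < 0:
            raise ValueError("noise and resolution must be non-negative")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    n_strokes: int
    stroke_times: np.ndarray
    stroke_peaks: np.ndarray
    stroke_subsession: np.ndarray
    subsession_spans: list[tuple[float, float]]
    pause_spans: list[tuple[float, float]]
    n_bursts: int
    contact_time: float
    applied_force: np.ndarray  # noise-free local applied force, master rate
    resultant: np.ndarray  # noise-free applied resultant, master rate
    euler: np.ndarray  # true attitude trajectory, master rate
    timestamp: np.ndarray
    cal: CalibrationParams

    def to_dict(self) -> dict:
        return {
            "n_strokes": int(self.n_strokes),
            "stroke_times": self.stroke_times.tolist(),
            "stroke_peaks": self.stroke_peaks.tolist(),
            "stroke_subsession": self.stroke_subsession.tolist(),
            "subsession_spans": [list(map(float, s)) for s in self.subsession_spans],
            "pause_spans": [list(map(float, s)) for s in self.pause_spans],
            "n_bursts": int(self.n_bursts),
            "contact_time": float(self.contact_time),
        }


def true_offsets(
    cal: CalibrationParams, split: float = 0.5
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact no-load offsets and blade-tension shift implied by the model."""
    tension = np.array([0.0, 0.0, cal.blade_weight])
    v_left = cal.v_zero_left + np.linalg.solve(cal.a_left, split * tension)
    v_right = cal.v_zero_right + np.linalg.solve(cal.a_right, (1 - split) * tension)
    xi = 0.5 * (
        (v_left[2] - cal.v_zero_left[2]) + (v_right[2] - cal.v_zero_right[2])
    )
    return v_left, v_right, float(xi)


def make_noise(
    sigma_v: float,
    resolution_v: float,
    size,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gaussian channel noise snapped to the ADC resolution grid."""
    if sigma_v < 0:
        raise ValueError("sigma must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, sigma_v, size) if sigma_v > 0 else np.zeros(size)
    if resolution_v > 0:
        noise = np.round(noise / resolution_v) * resolution_v
    return noise


def _azimuths(script: StrokeScript) -> np.ndarray:
    """Planar force azimuth (degrees from local x) per stroke."""
    k = np.arange(script.n_strokes)
    if script.pattern == "linear_cross_fiber":
        return np.where(k % 2 == 0, 90.0, 270.0)
    if script.pattern == "scanning":
        return np.full(script.n_strokes, 90.0)
    if script.pattern == "fanning_curvilinear":
        if script.n_strokes == 1:
            return np.array([90.0])
        return 50.0 + 80.0 * k / (script.n_strokes - 1)
    # sweeping: slow continuous progression
    return 90.0 + 15.0 * k


def _burst_profile(
    script: StrokeScript, master_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resultant magnitude, direction unit vectors, stroke times and true
    peaks for one burst, on the burst-local master-rate grid."""
    period = 1.0 / script.rate
    n_ticks = int(round(script.n_strokes * period * master_rate))
    t = np.arange(n_ticks) / master_rate
    cycle = np.minimum((t * script.rate).astype(int), script.n_strokes - 1)
    tau = t - cycle * period

    peaks = np.full(script.n_strokes, script.peak_force)
    if script.peak_jitter > 0:
        peaks *= 1.0 + script.peak_jitter * rng.uniform(-1, 1, script.n_strokes)

    amp = peaks[cycle] - script.baseline_force
    r = script.baseline_force + amp * np.sin(np.pi * tau / period)

    if script.ripple_amplitude > 0:
        center, width = 0.62 * period, 0.045 * period
        r = r + script.ripple_amplitude * np.exp(-0.5 * ((tau - center) / width) ** 2)
    if script.vibration_amplitude > 0:
        envelope = np.clip(amp, 0, None) / max(script.peak_force, 1e-9)
        r = r + script.vibration_amplitude * envelope * np.sin(
            2 * np.pi * script.vibration_freq * t
        )

    az = np.radians(_azimuths(script))[cycle]
    if script.pattern == "sweeping":
        az = az + np.pi * tau / period * 0.5
    alpha = math.radians(script.planar_angle)
    d = np.column_stack(
        [
            np.sin(alpha) * np.cos(az),
            np.sin(alpha) * np.sin(az),
            np.full(n_ticks, math.cos(alpha)),
        ]
    )

    # true per-cycle crest of the noise-free resultant
    stroke_times = np.empty(script.n_strokes)
    stroke_peaks = np.empty(script.n_strokes)
    for k in range(script.n_strokes):
        sel = np.flatnonzero(cycle == k)
        j = sel[np.argmax(r[sel])]
        stroke_times[k] = t[j]
        stroke_peaks[k] = r[j]
    return r, d, stroke_times, stroke_peaks


def simulate_session(script: SessionScript) -> tuple[RawStream, GroundTruth]:
    """Generate the raw device stream for a scripted session.

    The stream starts with the calibration window (device at identity
    attitude, no applied force), a button press into the ready state,
    then the scripted sub-sessions separated by button-paused intervals;
    a final press closes the session.  Identical scripts and seeds yield
    bit-identical streams.
    """
    rng = np.random.default_rng(script.seed)
    cal = script.cal
    fs = cal.master_rate
    dt = 1.0 / fs
    press_ticks = max(1, int(round(0.05 * fs)))

    resultant: list[np.ndarray] = []
    direction: list[np.ndarray] = []
    button_events: list[int] = []  # tick indices of press edges
    stroke_times: list[float] = []
    stroke_peaks: list[float] = []
    stroke_sub: list[int] = []
    sub_spans: list[tuple[float, float]] = []
    pause_spans: list[tuple[float, float]] = []
    n_bursts = 0

    def extend_flat(duration: float, force: float) -> None:
        n = int(round(duration * fs))
        resultant.append(np.full(n, force))
        direction.append(np.tile([0.0, 0.0, 1.0], (n, 1)))

    def ticks() -> int:
        return sum(len(r) for r in resultant)

    # calibration window, then button press -> ready
    extend_flat(script.calibration_duration, 0.0)
    button_events.append(ticks())

    for si, bursts in enumerate(script.subsessions):
        start = ticks() * dt
        extend_flat(script.lead_time, bursts[0].baseline_force)
        for bi, stroke_script in enumerate(bursts):
            if bi > 0:
                extend_flat(script.burst_gap, stroke_script.baseline_force)
            offset = ticks() * dt
            r, d, st, sp = _burst_profile(stroke_script, fs, rng)
            resultant.append(r)
            direction.append(d)
            stroke_times.extend((offset + st).tolist())
            stroke_peaks.extend(sp.tolist())
            stroke_sub.extend([si] * len(st))
            n_bursts += 1
        extend_flat(script.lead_time, bursts[-1].baseline_force)
        sub_spans.append((start, ticks() * dt))

        button_events.append(ticks())  # press -> pause
        if si < len(script.subsessions) - 1:
            pause_start = ticks() * dt
            extend_flat(script.pause_duration, 0.0)
            pause_spans.append((pause_start, ticks() * dt))
            button_events.append(ticks())  # press -> ready
    extend_flat(0.5, 0.0)  # trailing paused tail

    r_all = np.concatenate(resultant)
    d_all = np.vstack(direction)
    n = len(r_all)
    t = np.arange(n) * dt

    # attitude trajectory (identity through calibration)
    t_motion = np.maximum(0.0, t - script.calibration_duration)
    euler = script.orientation.euler_deg(t_motion)
    rot = _rotations(euler)

    # gyro: interval-centred body rates; accel: gravity direction in body frame
    t_mid = np.maximum(0.0, t_motion - 0.5 * dt)
    gyro = _body_rates(script.orientation.euler_deg(t_mid),
                       script.orientation.euler_rate_deg(t_mid))
    gyro[t_motion <= 0.0] = 0.0  # device at rest through calibration
    gravity_body = rot[:, 2, :]  # R^T @ (0,0,1) row-wise
    accel = gravity_body.copy()
    if script.gyro_noise > 0:
        gyro = gyro + rng.normal(0.0, script.gyro_noise, gyro.shape)
    if script.accel_noise > 0:
        accel = accel + rng.normal(0.0, script.accel_noise, accel.shape)

    f_applied = r_all[:, None] * d_all
    tension_local = cal.blade_weight * gravity_body
    f_total = f_applied + tension_local

    inv_left = np.linalg.inv(cal.a_left)
    inv_right = np.linalg.inv(cal.a_right)
    v_left = cal.v_zero_left + (script.split * f_total) @ inv_left.T
    v_right = cal.v_zero_right + ((1 - script.split) * f_total) @ inv_right.T
    if script.noise_v > 0:
        v_left = v_left + rng.normal(0.0, script.noise_v, v_left.shape)
        v_right = v_right + rng.normal(0.0, script.noise_v, v_right.shape)
    if script.adc_resolution > 0:
        res = script.adc_resolution
        v_left = np.round(v_left / res) * res
        v_right = np.round(v_right / res) * res

    button = np.zeros(n, dtype=bool)
    for e in button_events:
        button[e : min(e + press_ticks, n)] = True

    stream = RawStream(
        timestamp=t,
        v_left=v_left,
        v_right=v_right,
        accel=accel,
        gyro=gyro,
        button=button,
        rate=fs,
    )
    truth = GroundTruth(
        n_strokes=len(stroke_times),
        stroke_times=np.asarray(stroke_times),
        stroke_peaks=np.asarray(stroke_peaks),
        stroke_subsession=np.asarray(stroke_sub, dtype=int),
        subsession_spans=sub_spans,
        pause_spans=pause_spans,
        n_bursts=n_bursts,
        contact_time=float(np.sum(r_all > 1.0) * dt),
        applied_force=f_applied,
        resultant=r_all,
        euler=euler,
        timestamp=t,
        cal=cal,
    )
    return stream, truth


def simulate_static_orientation(
    euler: EulerAngles,
    duration: float,
    cal: CalibrationParams | None = None,
    noise_v: float = 2.5e-5,
    adc_resolution: float = 2.5e-5,
    accel_noise: float = 2e-3,
    split: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> RawStream:
    """No-applied-load stream at one fixed attitude (gravity-residual tests)."""
    cal = cal or default_calibration()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(duration * cal.master_rate))
    t = np.arange(n) / cal.master_rate
    r = rotation_matrix_zyx(euler)
    gravity_body = r.T @ np.array([0.0, 0.0, 1.0])
    tension = cal.blade_weight * gravity_body

    v_left = cal.v_zero_left + np.linalg.solve(cal.a_left, split * tension)
    v_right = cal.v_zero_right + np.linalg.solve(cal.a_right, (1 - split) * tension)
    v_left = np.tile(v_left, (n, 1))
    v_right = np.tile(v_right, (n, 1))
    if noise_v > 0:
        v_left = v_left + rng.normal(0.0, noise_v, v_left.shape)
        v_right = v_right + rng.normal(0.0, noise_v, v_right.shape)
    if adc_resolution > 0:
        v_left = np.round(v_left / adc_resolution) * adc_resolution
        v_right = np.round(v_right / adc_resolution) * adc_resolution

    accel = np.tile(gravity_body, (n, 1))
    if accel_noise > 0:
        accel = accel + rng.normal(0.0, accel_noise, accel.shape)
    return RawStream(
        timestamp=t,
        v_left=v_left,
        v_right=v_right,
        accel=accel,
        gyro=np.zeros((n, 3)),
        button=np.zeros(n, dtype=bool),
        rate=cal.master_rate,
    )
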