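"""Device-characterization validation suite.

Recomputes the headline bench claims of the processing chain on the
synthetic device: stroke-count accuracy on smooth and uneven-contour
sessions, the gravity-corrected no-load residual over random
orientations, the stroke-rate fidelity ceiling, quaternion norm
conservation, and steady-motion attitude tracking error.  Each check
returns ``(value, n)`` where ``n`` is the problem size used; the checks
are deterministic given a base seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from .force import process_stream
from .orientation import AhrsConfig, EulerAngles, MadgwickAhrs
from .pipeline import run_session
from .simulator import (
    SessionScript,
    SinusoidalSweep,
    StrokeScript,
    default_calibration,
    simulate_static_orientation,
    true_offsets,
)

__all__ = [
    "smooth_session_accuracy",
    "contour_session_accuracy",
    "gravity_residual",
    "max_tracked_rate",
    "quaternion_norm_worst",
    "steady_motion_error",
    "run_all",
]


def _seed(base: int, k: int) -> int:
    return (base * 100003 + k) % (2**31 - 1)


def _count_accuracy(script: SessionScript) -> float:
    from .simulator import simulate_session

    stream, truth = simulate_session(script)
    result = run_session(stream, script.cal)
    detected = result.report.n_strokes
    return 100.0 * (1.0 - abs(detected - truth.n_strokes) / truth.n_strokes)


def _smooth_script(seed: int) -> SessionScript:
    """Smooth-surface, slow-paced session: 30 strokes, 0.5-1.5 Hz,
    10-40 N peaks, no orientation sweeps, only mild ripple and noise."""
    rng = np.random.default_rng(seed)
    peak = rng.uniform(10.0, 40.0)
    burst = StrokeScript(
        pattern="linear_cross_fiber",
        peak_force=peak,
        rate=float(rng.uniform(0.5, 1.5)),
        n_strokes=30,
        ripple_amplitude=float(rng.uniform(0.0, 0.04)) * peak,
        vibration_amplitude=0.3,
        peak_jitter=0.05,
    )
    return SessionScript(subsessions=[[burst]], seed=seed)


def _contour_script(seed: int) -> SessionScript:
    """Uneven-contour session: ±45° roll / ±25° pitch sweeps, redundant
    ripple bumps at 10-25 % of the peak force, pace varying 0.5-3 Hz."""
    rng = np.random.default_rng(seed)
    bursts = []
    for _ in range(3):
        peak = float(rng.uniform(10.0, 40.0))
        bursts.append(
            StrokeScript(
                pattern=str(rng.choice(["linear_cross_fiber", "fanning_curvilinear"])),
                peak_force=peak,
                rate=float(rng.uniform(0.5, 3.0)),
                n_strokes=10,
                ripple_amplitude=float(rng.uniform(0.10, 0.25)) * peak,
                vibration_amplitude=0.4,
                peak_jitter=0.10,
            )
        )
    sweep = SinusoidalSweep(
        amplitude=(10.0, 25.0, 45.0), freq_hz=float(rng.uniform(0.10, 0.20))
    )
    return SessionScript(subsessions=[bursts], orientation=sweep, seed=seed)


def smooth_session_accuracy(seed: int, n_sessions: int = 20) -> tuple[float, int]:
    """Mean stroke-count accuracy (%) over smooth, slow-paced sessions."""
    accs = [
        _count_accuracy(_smooth_script(_seed(seed, i))) for i in range(1, n_sessions + 1)
    ]
    return float(np.mean(accs)), n_sessions


def contour_session_accuracy(seed: int, n_sessions: int = 20) -> tuple[float, int]:
    """Mean stroke-count accuracy (%) over uneven-contour sessions."""
    accs = [
        _count_accuracy(_contour_script(_seed(seed, 20 + i)))
        for i in range(1, n_sessions + 1)
    ]
    return float(np.mean(accs)), n_sessions


def gravity_residual(seed: int, n_orientations: int = 1000) -> tuple[float, int]:
    """Max over axes of the mean |gravity-corrected force| (N) on no-load
    streams at uniformly random attitudes with ADC-level channel noise."""
    rng = np.random.default_rng(_seed(seed, 7))
    cal = default_calibration()
    off_l, off_r, xi = true_offsets(cal)
    import dataclasses

    cal = dataclasses.replace(cal, v_off_left=off_l, v_off_right=off_r, xi=xi)
    ahrs = AhrsConfig(update_rate=cal.ahrs_rate)

    per_axis = np.zeros(3)
    for _ in range(n_orientations):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        yaw, pitch, roll = Rotation.from_quat(
            [q[1], q[2], q[3], q[0]]
        ).as_euler("ZYX", degrees=True)
        stream = simulate_static_orientation(
            EulerAngles(yaw, pitch, roll), duration=0.5, cal=cal, rng=rng
        )
        filt = MadgwickAhrs(ahrs)
        initial = filt.initialize_from_accel(stream.accel[:25].mean(axis=0))
        out = process_stream(stream, cal, ahrs, initial=initial)
        tail = out.f_corrected[len(out) // 2 :]
        per_axis += np.mean(np.abs(tail), axis=0)
    per_axis /= n_orientations
    return float(per_axis.max()), n_orientations


def max_tracked_rate(seed: int, duration: float = 60.0) -> tuple[float, int]:
    """Highest scripted stroke rate (Hz) counted within 1 %, scanning
    0.5-5.0 Hz trains in 0.5 Hz steps."""
    rates = np.arange(0.5, 5.01, 0.5)
    best = 0.0
    for rate in rates:
        n_strokes = int(round(rate * duration))
        burst = StrokeScript(
            pattern="linear_cross_fiber",
            peak_force=20.0,
            rate=float(rate),
            n_strokes=n_strokes,
            vibration_amplitude=0.3,
        )
        script = SessionScript(subsessions=[[burst]], seed=_seed(seed, 11))
        from .simulator import simulate_session

        stream, truth = simulate_session(script)
        result = run_session(stream, script.cal)
        err = abs(result.report.n_strokes - truth.n_strokes) / truth.n_strokes
        if err <= 0.01:
            best = float(rate)
        else:
            break
    return best, len(rates)


def quaternion_norm_worst(seed: int, n_updates: int = 10000) -> tuple[float, int]:
    """Quaternion norm after random bounded updates: the norm at the step
    of worst deviation from unity (1.0 when conservation is exact)."""
    rng = np.random.default_rng(_seed(seed, 3))
    filt = MadgwickAhrs(AhrsConfig(beta=1.0, update_rate=200.0))
    worst = 1.0
    for _ in range(n_updates):
        gyro = rng.uniform(-4.0, 4.0, 3)
        accel = rng.normal(0.0, 1.0, 3)
        q = filt.update(gyro, accel)
        n = q.norm
        if abs(n - 1.0) > abs(worst - 1.0):
            worst = n
    return float(worst), n_updates


def steady_motion_error(
    seed: int,
    freqs=(0.5, 1.0, 2.0, 5.0),
    amplitude_deg: float = 30.0,
    duration: float = 30.0,
) -> tuple[float, int]:
    """Worst-case steady-motion Euler tracking error (% of amplitude).

    Single-axis (roll) sinusoidal rotations with analytically consistent
    200 Hz inertial streams plus mild sensor noise; the first 2 s of
    convergence are discarded.
    """
    rng = np.random.default_rng(_seed(seed, 5))
    fs = 200.0
    dt = 1.0 / fs
    amp = math.radians(amplitude_deg)
    worst = 0.0
    for f in freqs:
        n = int(duration * fs)
        t = np.arange(1, n + 1) * dt
        roll = amp * np.sin(2 * np.pi * f * t)
        # rate-integrating gyro: body rate at the sample-interval midpoint
        t_mid = t - 0.5 * dt
        gyro = np.zeros((n, 3))
        gyro[:, 0] = amp * 2 * np.pi * f * np.cos(2 * np.pi * f * t_mid)
        accel = np.column_stack(
            [np.zeros(n), np.sin(roll), np.cos(roll)]
        )  # R^T @ (0,0,1) for a pure roll
        gyro += rng.normal(0.0, 2e-3, gyro.shape)
        accel += rng.normal(0.0, 2e-3, accel.shape)

        filt = MadgwickAhrs(AhrsConfig(beta=1.0, update_rate=fs))
        est = np.empty((n, 3))
        for i in range(n):
            filt.update(gyro[i], accel[i])
            e = filt.euler
            est[i] = (e.yaw, e.pitch, e.roll)
        keep = t > 2.0
        true = np.column_stack([np.zeros(n), np.zeros(n), np.degrees(roll)])
        err = np.max(np.abs(est[keep] - true[keep]), axis=0)
        worst = max(worst, float(err.max() / amplitude_deg * 100.0))
    return worst, len(freqs)


def run_all(seed: int, quick: bool = False) -> dict[str, dict]:
    """All validation targets as ``{id: {"value": v, "n": n}}``."""
    n_sessions = 5 if quick else 20
    n_orient = 200 if quick else 1000
    duration = 20.0 if quick else 60.0
    results = {}
    for key, (value, n) in {
        "t1": smooth_session_accuracy(seed, n_sessions),
        "t2": contour_session_accuracy(seed, n_sessions),
        "t3": gravity_residual(seed, n_orient),
        "t4": max_tracked_rate(seed, duration),
        "t5": quaternion_norm_worst(seed),
        "t6": steady_motion_error(seed),
    }.items():
        results[key] = {"value": value, "n": n}
    return results
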