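"""End-to-end session processing: raw stream in, treatment report out.

Ties the chain together in firmware order: the calibration window at the
head of the stream fixes voltage offsets, the blade-tension shift, gyro
biases and the initial attitude; the force engine then produces the
100 Hz gravity-corrected stream; the state machine yields contact
accounting and sub-session spans; and stroke detection plus burst
segmentation feed the session report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .force import (
    CalibrationParams,
    ForceStream,
    RawStream,
    compute_voltage_offsets,
    process_stream,
)
from .orientation import AhrsConfig, MadgwickAhrs, Quaternion
from .report import TreatmentReport, build_report
from .session import TimeLedger, track_session
from .strokes import (
    Burst,
    FilterConfig,
    StrokeEvent,
    detect_strokes,
    label_burst_pattern,
    segment_bursts,
)

__all__ = ["AnalysisConfig", "SessionResult", "calibrate", "run_session"]


@dataclass
class AnalysisConfig:
    """Post-processing settings: smoothing, contact logic, burst splitting."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    contact_threshold: float = 1.0
    debounce: int = 3
    max_gap: float = 2.0
    freq_tolerance: float = 0.35

    def to_dict(self) -> dict:
        return {
            "kernel": self.filter.kernel,
            "binomial_n": self.filter.binomial_n,
            "butter_order": self.filter.butter_order,
            "butter_cutoff": self.filter.butter_cutoff,
            "confidence_band": list(self.filter.confidence_band),
            "min_prominence": self.filter.min_prominence,
            "contact_threshold": self.contact_threshold,
            "debounce": self.debounce,
            "max_gap": self.max_gap,
            "freq_tolerance": self.freq_tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        filt = FilterConfig(
            kernel=d.get("kernel", "binomial"),
            binomial_n=int(d.get("binomial_n", 25)),
            butter_order=int(d.get("butter_order", 10)),
            butter_cutoff=float(d.get("butter_cutoff", 11.0)),
            confidence_band=tuple(d.get("confidence_band", (0.33, 3.0))),
            min_prominence=float(d.get("min_prominence", 1.0)),
        )
        return cls(
            filter=filt,
            contact_threshold=float(d.get("contact_threshold", 1.0)),
            debounce=int(d.get("debounce", 3)),
            max_gap=float(d.get("max_gap", 2.0)),
            freq_tolerance=float(d.get("freq_tolerance", 0.35)),
        )


@dataclass
class SessionResult:
    """Everything produced while processing one session."""

    stream: ForceStream
    states: np.ndarray
    ledger: TimeLedger
    subsessions: list[tuple[int, int]]
    strokes: list[StrokeEvent]
    bursts: list[Burst]
    report: TreatmentReport


def calibrate(
    stream: RawStream,
    cal: CalibrationParams,
    ahrs: AhrsConfig | None = None,
    prelude_end: int | None = None,
) -> tuple[CalibrationParams, np.ndarray, Quaternion]:
    """Fit offsets, ξ, gyro bias and initial attitude from the calibration
    window at the head of the stream.

    The window runs to the first button press (or ``prelude_end``); its
    first 20 % is discarded as settling time.  Returns an updated copy of
    the calibration parameters plus the gyro bias vector and the
    converged initial quaternion.
    """
    if prelude_end is None:
        edges = np.flatnonzero(stream.button[1:] & ~stream.button[:-1]) + 1
        if stream.button[0]:
            prelude_end = 0
        else:
            prelude_end = int(edges[0]) if edges.size else len(stream)
    if prelude_end < 10:
        raise ValueError("calibration window too short")
    lo = prelude_end // 5
    v_l = stream.v_left[lo:prelude_end]
    v_r = stream.v_right[lo:prelude_end]
    off_l, off_r, xi = compute_voltage_offsets(
        v_l, v_r, cal.v_zero_left, cal.v_zero_right
    )
    fitted = dataclasses.replace(cal, v_off_left=off_l, v_off_right=off_r, xi=xi)

    gyro_bias = stream.gyro[lo:prelude_end].mean(axis=0)
    accel_mean = stream.accel[lo:prelude_end].mean(axis=0)
    ahrs = ahrs or AhrsConfig(update_rate=cal.ahrs_rate)
    filt = MadgwickAhrs(ahrs)
    filt.initialize_from_accel(accel_mean)
    # refine on the calibration-window samples at the fusion cadence
    step = max(1, int(round(cal.master_rate / cal.ahrs_rate)))
    for i in range(lo, prelude_end, step):
        filt.update(stream.gyro[i] - gyro_bias, stream.accel[i])
    return fitted, gyro_bias, filt.quaternion


def run_session(
    stream: RawStream,
    cal: CalibrationParams,
    ahrs: AhrsConfig | None = None,
    analysis: AnalysisConfig | None = None,
    user_target: float | None = None,
) -> SessionResult:
    """Process one raw session stream into a treatment report.

    When the calibration parameters carry no measured offsets, the
    stream's own calibration window is used to fit them.
    """
    analysis = analysis or AnalysisConfig()
    ahrs = ahrs or AhrsConfig(update_rate=cal.ahrs_rate)

    if cal.v_off_left is None or cal.v_off_right is None:
        cal, gyro_bias, q0 = calibrate(stream, cal, ahrs)
    else:
        gyro_bias, q0 = np.zeros(3), None

    fstream = process_stream(stream, cal, ahrs, gyro_bias=gyro_bias, initial=q0)
    states, ledger, subsessions = track_session(
        fstream.f_rms,
        fstream.button,
        fstream.dt,
        contact_threshold=analysis.contact_threshold,
        debounce=analysis.debounce,
    )

    strokes: list[StrokeEvent] = []
    subsession_ids: list[int] = []
    for si, (lo, hi) in enumerate(subsessions):
        seg = fstream.f_rms[lo : hi + 1]
        events = detect_strokes(
            seg,
            fstream.rate,
            analysis.filter,
            raw=seg,
            index_offset=lo,
            time_offset=float(fstream.timestamp[lo]),
        )
        strokes.extend(events)
        subsession_ids.extend([si] * len(events))

    bursts = segment_bursts(
        strokes,
        max_gap=analysis.max_gap,
        freq_tolerance=analysis.freq_tolerance,
        subsession_ids=subsession_ids,
    )
    for b in bursts:
        b.pattern_label = label_burst_pattern(b, fstream.f_corrected, fstream.euler)

    report = build_report(
        fstream,
        strokes,
        bursts,
        ledger,
        states,
        n_subsessions=len(subsessions),
        user_target=user_target,
    )
    return SessionResult(
        stream=fstream,
        states=states,
        ledger=ledger,
        subsessions=subsessions,
        strokes=strokes,
        bursts=bursts,
        report=report,
    )
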