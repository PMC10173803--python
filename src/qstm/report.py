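"""Session-level treatment parameter aggregation.

Condenses one processed session into the clinician-facing dose metrics:
average compressive and resultant forces over skin-contact time, the
maximum and mean stroke peak forces (the latter is the delivered *target
force*, compared with the user-defined target when one is set), stroke
and burst counts, contact/elapsed times, stroke frequency, and the mean
application angle of the blade's compressive axis relative to the
treatment plane.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .force import ForceStream
from .session import State, TimeLedger
from .strokes import Burst, StrokeEvent, stroke_frequency

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = ["TreatmentReport", "build_report"]


@dataclass(frozen=True)
class TreatmentReport:
    """Aggregated treatment parameters for one session (forces in N)."""

    avg_compressive_force: float
    avg_resultant_force: float
    max_peak_force: float
    target_force: float
    n_strokes: int
    n_bursts: int
    n_subsessions: int
    contact_time: float
    elapsed_time: float
    stroke_frequency: float
    stroke_frequency_contact: float
    avg_application_angle: float
    user_target: float | None = None
    target_deviation: float | None = None
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "avg_compressive_force": self.avg_compressive_force,
            "avg_resultant_force": self.avg_resultant_force,
            "max_peak_force": self.max_peak_force,
            "target_force": self.target_force,
            "n_strokes": self.n_strokes,
            "n_bursts": self.n_bursts,
            "n_subsessions": self.n_subsessions,
            "contact_time": self.contact_time,
            "elapsed_time": self.elapsed_time,
            "stroke_frequency": self.stroke_frequency,
            "stroke_frequency_contact": self.stroke_frequency_contact,
            "avg_application_angle": self.avg_application_angle,
        }
        if self.user_target is not None:
            d["user_target"] = self.user_target
            d["target_deviation"] = self.target_deviation
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _application_angle(quat: np.ndarray) -> np.ndarray:
    """Per-tick application angle in degrees.

    Defined as 90° minus the elevation of the blade's compressive (local
    z) axis above the global horizontal plane: 0° when the device is
    upright in its calibration pose, growing as the blade tilts toward
    the skin plane.
    """
    q = np.atleast_2d(np.asarray(quat, dtype=float))
    q0, q1, q2, q3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # global-z component of the rotated local z axis (R[2,2])
    zz = q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3
    elevation = np.degrees(np.arcsin(np.clip(np.abs(zz), 0.0, 1.0)))
    return 90.0 - elevation


def build_report(
    force_states: ForceStream,
    strokes: Sequence[StrokeEvent],
    bursts: Sequence[Burst],
    ledger: TimeLedger,
    states: np.ndarray,
    n_subsessions: int,
    user_target: float | None = None,
) -> TreatmentReport:
    """Aggregate QSTM treatment parameters from one processed session.

    Averages are taken over operational (skin-contact) ticks only, since
    the dose is undefined off-skin; the compressive average uses |Fz|.  A
    session with no operational ticks yields a zero report with a logged
    warning.
    """
    op = np.asarray([int(s) for s in states]) == int(State.OPERATIONAL)
    if not op.any():
        logger.warning("no operational ticks in session; reporting zeros")
        avg_fz = avg_frms = avg_angle = 0.0
    else:
        avg_fz = float(np.mean(np.abs(force_states.f_corrected[op, 2])))
        avg_frms = float(np.mean(force_states.f_rms[op]))
        avg_angle = float(np.mean(_application_angle(force_states.quat[op])))

    peak_forces = np.array([s.peak_force for s in strokes], dtype=float)
    max_peak = float(peak_forces.max()) if peak_forces.size else 0.0
    target = float(peak_forces.mean()) if peak_forces.size else 0.0

    if ledger.elapsed_time > 0:
        rate = stroke_frequency(len(strokes), ledger)
        freq, freq_contact = rate.treatment_rate, rate.contact_rate
    else:
        freq = freq_contact = 0.0

    return TreatmentReport(
        avg_compressive_force=avg_fz,
        avg_resultant_force=avg_frms,
        max_peak_force=max_peak,
        target_force=target,
        n_strokes=len(strokes),
        n_bursts=len(bursts),
        n_subsessions=n_subsessions,
        contact_time=ledger.contact_time,
        elapsed_time=ledger.elapsed_time,
        stroke_frequency=freq,
        stroke_frequency_contact=freq_contact,
        avg_application_angle=avg_angle,
        user_target=user_target,
        target_deviation=(target - user_target) if user_target is not None else None,
    )
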