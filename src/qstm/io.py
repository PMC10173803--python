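"""File formats: raw-stream CSV dialects, YAML configuration, reports.

Two versioned CSV dialects carry device streams, each tagged by a header
comment line so readers can dispatch without guessing:

``#qstm-dialect: v1-voltage``
    Pre-calibration streams at the master rate: timestamp, the two
    load-cell voltage triples, IMU vectors and the button state.

``#qstm-dialect: v1-processed``
    The 100 Hz processed message stream: timestamp, gravity-corrected 3-D
    force, resultant force, yaw/pitch/roll, IMU vectors, button state.

Numeric fields survive a write/read round trip to at least six
significant digits.  All logging goes to stderr; files carry results
only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .force import CalibrationParams, ForceStream, RawStream
from .orientation import AhrsConfig
from .pipeline import AnalysisConfig
from .simulator import GroundTruth
from .strokes import Burst, StrokeEvent

__all__ = [
    "DIALECT_VOLTAGE",
    "DIALECT_PROCESSED",
    "write_raw_csv",
    "write_processed_csv",
    "read_raw_csv",
    "load_config",
    "save_config",
    "save_ground_truth",
    "write_stroke_table",
]

DIALECT_VOLTAGE = "v1-voltage"
DIALECT_PROCESSED = "v1-processed"
_FLOAT_FMT = "%.8g"

_VOLTAGE_COLS = [
    "timestamp",
    "Vlx", "Vly", "Vlz",
    "Vrx", "Vry", "Vrz",
    "ax", "ay", "az",
    "gx", "gy", "gz",
    "button",
]
_PROCESSED_COLS = [
    "timestamp",
    "Fx", "Fy", "Fz", "Frms",
    "yaw", "pitch", "roll",
    "ax", "ay", "az",
    "gx", "gy", "gz",
    "button",
]


def write_raw_csv(stream: RawStream, path: str | Path) -> None:
    """Write a raw voltage-dialect stream."""
    df = pd.DataFrame(
        np.column_stack(
            [
                stream.timestamp,
                stream.v_left,
                stream.v_right,
                stream.accel,
                stream.gyro,
                stream.button.astype(int),
            ]
        ),
        columns=_VOLTAGE_COLS,
    )
    df["button"] = df["button"].astype(int)
    with open(path, "w") as fh:
        fh.write(f"#qstm-dialect: {DIALECT_VOLTAGE}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_processed_csv(stream: ForceStream, path: str | Path) -> None:
    """Write a processed-dialect stream (the 100 Hz message string)."""
    df = pd.DataFrame(
        np.column_stack(
            [
                stream.timestamp,
                stream.f_corrected,
                stream.f_rms,
                stream.euler,
                stream.accel,
                stream.gyro,
                stream.button.astype(int),
            ]
        ),
        columns=_PROCESSED_COLS,
    )
    df["button"] = df["button"].astype(int)
    with open(path, "w") as fh:
        fh.write(f"#qstm-dialect: {DIALECT_PROCESSED}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first:
        raise ValueError(f"{path}: no header")
    if first.startswith("#qstm-dialect:"):
        return first.split(":", 1)[1].strip()
    raise ValueError(
        f"{path}: missing dialect header; expected '#qstm-dialect: "
        f"{DIALECT_VOLTAGE}|{DIALECT_PROCESSED}'"
    )


def read_raw_csv(path: str | Path, dialect: str | None = None):
    """Read a device CSV; returns a :class:`RawStream` for the voltage
    dialect or a :class:`ForceStream` for the processed dialect.

    Malformed (non-numeric) rows are rejected with their line numbers.
    """
    path = Path(path)
    found = _sniff_dialect(path)
    if dialect is not None and dialect != found:
        raise ValueError(f"{path}: dialect {found!r}, expected {dialect!r}")
    expected = _VOLTAGE_COLS if found == DIALECT_VOLTAGE else _PROCESSED_COLS
    df = pd.read_csv(path, skiprows=1)
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: unknown header {list(df.columns)}; expected {expected}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 3 for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    df = numeric

    ts = df["timestamp"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 500.0
    if found == DIALECT_VOLTAGE:
        return RawStream(
            timestamp=ts,
            v_left=df[["Vlx", "Vly", "Vlz"]].to_numpy(),
            v_right=df[["Vrx", "Vry", "Vrz"]].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            button=df["button"].to_numpy() > 0.5,
            rate=rate,
        )
    f = df[["Fx", "Fy", "Fz"]].to_numpy()
    n = len(ts)
    return ForceStream(
        timestamp=ts,
        f_local=np.full((n, 3), np.nan),
        f_corrected=f,
        f_rms=df["Frms"].to_numpy(),
        quat=np.full((n, 4), np.nan),
        euler=df[["yaw", "pitch", "roll"]].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        button=df["button"].to_numpy() > 0.5,
        rate=rate,
    )


def load_config(path: str | Path) -> tuple[CalibrationParams, AhrsConfig, AnalysisConfig]:
    """Load device configuration (YAML or JSON) and validate it."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "calibration" not in d:
        raise ValueError(f"{path}: config must contain a 'calibration' section")
    cal = CalibrationParams.from_dict(d["calibration"])
    ahrs_d = d.get("ahrs", {})
    ahrs = AhrsConfig(
        beta=float(ahrs_d.get("beta", 1.0)),
        update_rate=float(ahrs_d.get("update_rate", cal.ahrs_rate)),
    )
    analysis = AnalysisConfig.from_dict(d.get("analysis", {}))
    return cal, ahrs, analysis


def save_config(
    path: str | Path,
    cal: CalibrationParams,
    ahrs: AhrsConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> None:
    ahrs = ahrs or AhrsConfig(update_rate=cal.ahrs_rate)
    analysis = analysis or AnalysisConfig()
    d = {
        "calibration": cal.to_dict(),
        "ahrs": {"beta": ahrs.beta, "update_rate": ahrs.update_rate},
        "analysis": analysis.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar JSON of scripted stroke times, peaks and session structure."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def write_stroke_table(
    strokes: list[StrokeEvent], bursts: list[Burst], path: str | Path
) -> None:
    """Per-stroke CSV: peak force, time, duration, burst id."""
    burst_of = {}
    for bi, b in enumerate(bursts):
        for s in b.strokes:
            burst_of[s.peak_index] = bi
    rows = [
        {
            "peak_time_s": s.peak_time,
            "peak_force_N": s.peak_force,
            "duration_s": s.duration,
            "burst": burst_of.get(s.peak_index, -1),
        }
        for s in strokes
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
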