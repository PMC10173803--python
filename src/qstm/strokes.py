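"""Stroke detection and treatment-rate estimation from the resultant force.

A treatment stroke is one force-motion cycle, identified by the maximum
resultant force peak of the cycle.  The resultant (dose-load) stream is
low-pass filtered, local maxima/minima are extracted from the sign
changes of its first difference, and redundant peaks — shoulder ripples
from hand vibration or tissue irregularities riding on a stroke hill —
are discarded by thresholding the *confidence ratio* of every
valley→peak→next-valley triple (rise over fall).  Triples whose ratio
falls outside the configured band are merged into the adjacent cycle
until every surviving stroke is a well-formed cycle.

Two smoothing kernels are provided: the binomial-kernel filter (default,
window 25 — better signal-to-noise for sporadic non-deterministic
motions) and a zero-phase order-10 Butterworth at 11 Hz cutoff (better
for steady motions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import comb

from .session import TimeLedger

__all__ = [
    "FilterConfig",
    "PeakValleyPair",
    "StrokeEvent",
    "Burst",
    "StrokeRate",
    "binomial_kernel",
    "binomial_lpf",
    "butterworth_lpf",
    "smooth",
    "find_peaks_valleys",
    "build_pairs",
    "confidence_ratio",
    "filter_redundant_peaks",
    "detect_strokes",
    "stroke_frequency",
    "segment_bursts",
    "label_burst_pattern",
]

_EPS = 1e-9


@dataclass
class FilterConfig:
    """Smoothing and decision-tree settings for stroke detection.

    ``confidence_band`` is the (low, high) acceptance interval for the
    rise/fall confidence ratio; symmetric strokes score ≈ 1 and must
    always pass, so ``low <= 1 <= high``.  ``min_prominence`` (N) keeps
    noise peaks in near-contactless segments out of the decision tree and
    defaults to the 1 N skin-contact threshold.
    """

    kernel: str = "binomial"
    binomial_n: int = 25
    butter_order: int = 10
    butter_cutoff: float = 11.0
    confidence_band: tuple[float, float] = (0.33, 3.0)
    min_prominence: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("binomial", "butterworth"):
            raise ValueError("kernel must be 'binomial' or 'butterworth'")
        low, high = self.confidence_band
        if not (low <= 1.0 <= high):
            raise ValueError("confidence band must contain 1")


class PeakValleyPair(NamedTuple):
    """One valley→peak→next-valley triple, as (index, force) tuples."""

    valley_i: tuple[int, float]
    peak_i: tuple[int, float]
    valley_next: tuple[int, float]


@dataclass(frozen=True)
class StrokeEvent:
    """One detected force-motion cycle (primary peak plus flanking valleys)."""

    peak_index: int
    peak_force: float
    start_index: int
    end_index: int
    duration: float
    peak_time: float = 0.0


@dataclass
class Burst:
    """A train of consecutive similar-paced strokes within one sub-session."""

    strokes: list[StrokeEvent]
    mean_frequency: float
    pattern_label: str = "unknown"


class StrokeRate(NamedTuple):
    """Stroke frequency per treatment time (canonical) and per contact time."""

    treatment_rate: float
    contact_rate: float


def binomial_kernel(n: int) -> np.ndarray:
    """Normalized binomial weights of window size ``n`` (row n-1 of Pascal's
    triangle), the discrete approximation to a Gaussian of σ ≈ √(n-1)/2."""
    if n < 1:
        raise ValueError("window must be >= 1")
    w = comb(n - 1, np.arange(n))
    return w / w.sum()


def binomial_lpf(f: np.ndarray, n: int = 25) -> np.ndarray:
    """Zero-phase low-pass by convolution with a binomial kernel.

    Edges are handled with renormalized truncated kernels so a constant
    stream passes through unchanged; output length equals input length.
    """
    f = np.asarray(f, dtype=float)
    w = binomial_kernel(n)
    start = (len(w) - 1) // 2
    num = np.convolve(f, w, mode="full")[start : start + len(f)]
    den = np.convolve(np.ones_like(f), w, mode="full")[start : start + len(f)]
    return num / den


def butterworth_lpf(
    f: np.ndarray, order: int = 10, cutoff_hz: float = 11.0, fs_hz: float = 100.0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass, DC gain 1.

    Designed directly in second-order sections, which keeps the high-order
    filter numerically stable.
    """
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    f = np.asarray(f, dtype=float)
    sos = butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    padlen = min(3 * (2 * order + 1), len(f) - 1)
    return sosfiltfilt(sos, f, padlen=max(padlen, 0))


def smooth(f: np.ndarray, fs_hz: float, config: FilterConfig) -> np.ndarray:
    if config.kernel == "binomial":
        return binomial_lpf(f, config.binomial_n)
    return butterworth_lpf(f, config.butter_order, config.butter_cutoff, fs_hz)


def find_peaks_valleys(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternating valleys and peaks from first-difference sign changes.

    Returns ``(valleys, peaks)`` index arrays with ``len(valleys) ==
    len(peaks) + 1``: the sequence starts and ends with a valley,
    inserting synthetic boundary valleys at the stream ends if needed.
    Flat extrema are assigned to the first sample of the plateau.
    """
    f = np.asarray(f, dtype=float)
    if len(f) < 3:
        raise ValueError("stream too short for peak-valley extraction")
    s = np.sign(np.diff(f))
    # backward-fill zeros so a plateau's extremum lands on its first sample,
    # then forward-fill any trailing zeros (flat tail)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.array([0, len(f) - 1]), np.array([], dtype=int)
    filled = s.copy()
    for i in range(len(filled) - 2, -1, -1):
        if filled[i] == 0:
            filled[i] = filled[i + 1]
    last = nz[-1]
    filled[last:] = s[last]

    extrema: list[tuple[int, bool]] = []  # (index, is_peak)
    for i in range(len(filled) - 1):
        if filled[i] > 0 and filled[i + 1] < 0:
            extrema.append((i + 1, True))
        elif filled[i] < 0 and filled[i + 1] > 0:
            extrema.append((i + 1, False))

    if not extrema:
        return np.array([0, len(f) - 1]), np.array([], dtype=int)
    if extrema[0][1]:  # starts with a peak: synthetic valley at stream start
        extrema.insert(0, (0, False))
    if extrema[-1][1]:  # ends with a peak: synthetic valley at stream end
        extrema.append((len(f) - 1, False))
    valleys = np.array([i for i, p in extrema if not p], dtype=int)
    peaks = np.array([i for i, p in extrema if p], dtype=int)
    return valleys, peaks


def build_pairs(
    f: np.ndarray, valleys: np.ndarray, peaks: np.ndarray
) -> list[PeakValleyPair]:
    f = np.asarray(f, dtype=float)
    return [
        PeakValleyPair(
            (int(valleys[i]), float(f[valleys[i]])),
            (int(peaks[i]), float(f[peaks[i]])),
            (int(valleys[i + 1]), float(f[valleys[i + 1]])),
        )
        for i in range(len(peaks))
    ]


def confidence_ratio(pair: PeakValleyPair) -> float:
    """Rise (valley→peak) over fall (peak→next valley); +inf when the fall
    is degenerate."""
    rise = pair.peak_i[1] - pair.valley_i[1]
    fall = pair.peak_i[1] - pair.valley_next[1]
    if fall < _EPS:
        return math.inf
    return rise / fall


def _band_violation(ratio: float, band: tuple[float, float]) -> float:
    """Severity of a ratio outside the band (0 when inside), measured on a
    log scale so rise- and fall-dominated offenders compare fairly."""
    low, high = band
    if ratio != ratio:  # NaN: degenerate rise and fall
        return math.inf
    if ratio == math.inf:
        return math.inf
    if ratio < low:
        return math.log(low / max(ratio, _EPS))
    if ratio > high:
        return math.log(ratio / high)
    return 0.0


def filter_redundant_peaks(
    f: np.ndarray,
    valleys: np.ndarray,
    peaks: np.ndarray,
    band: tuple[float, float] = (0.33, 3.0),
    min_prominence: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decision-tree elimination of redundant peaks.

    A peak whose confidence ratio falls outside ``band`` (or whose
    prominence is below ``min_prominence``) is redundant: its shallower
    flanking valley is deleted and the taller of the merged peaks is
    retained, so each surviving cycle keeps its maximum resultant peak.
    Merging repeats until every surviving triple lies inside the band;
    the operation is idempotent.
    """
    f = np.asarray(f, dtype=float)
    V = [int(i) for i in valleys]
    P = [int(i) for i in peaks]

    def merge(i: int, side: str) -> None:
        if side == "right":
            if i == len(P) - 1:
                # terminal peak with no cycle to absorb it: drop the peak and
                # the shallower of its flanking valleys
                shallower = i if f[V[i]] > f[V[i + 1]] else i + 1
                del P[i]
                del V[shallower]
            else:
                del V[i + 1]
                drop = i if f[P[i]] < f[P[i + 1]] else i + 1
                del P[drop]
        else:
            if i == 0:
                shallower = 0 if f[V[0]] > f[V[1]] else 1
                del P[0]
                del V[shallower]
            else:
                del V[i]
                drop = i - 1 if f[P[i - 1]] < f[P[i]] else i
                del P[drop]

    while P:
        rises = [f[P[i]] - f[V[i]] for i in range(len(P))]
        falls = [f[P[i]] - f[V[i + 1]] for i in range(len(P))]
        proms = [f[P[i]] - max(f[V[i]], f[V[i + 1]]) for i in range(len(P))]

        # low-prominence peaks (noise in near-contactless segments) first
        weak = [i for i in range(len(P)) if proms[i] < min_prominence]
        if weak:
            i = min(weak, key=lambda k: proms[k])
            merge(i, "right" if falls[i] <= rises[i] else "left")
            continue

        ratios = [
            math.inf if falls[i] < _EPS else rises[i] / falls[i]
            for i in range(len(P))
        ]
        scores = [_band_violation(r, band) for r in ratios]
        worst = max(range(len(P)), key=lambda k: scores[k])
        if scores[worst] <= 0.0:
            break
        merge(worst, "right" if ratios[worst] > band[1] else "left")

    return np.array(V, dtype=int), np.array(P, dtype=int)


def detect_strokes(
    f_rms: np.ndarray,
    fs_hz: float,
    config: FilterConfig | None = None,
    raw: np.ndarray | None = None,
    index_offset: int = 0,
    time_offset: float = 0.0,
) -> list[StrokeEvent]:
    """Full stroke extraction on one contiguous resultant-force segment.

    Smooths the stream, extracts peak-valley pairs, prunes redundant
    peaks, and reports one :class:`StrokeEvent` per surviving cycle.  When
    the unsmoothed stream is supplied via ``raw``, each stroke's peak
    force is the raw maximum over its valley-to-valley span (the maximum
    resultant peak force of the cycle, undistorted by smoothing).
    """
    config = config or FilterConfig()
    f_rms = np.asarray(f_rms, dtype=float)
    if len(f_rms) < 3:
        return []
    sm = smooth(f_rms, fs_hz, config)
    valleys, peaks = find_peaks_valleys(sm)
    valleys, peaks = filter_redundant_peaks(
        sm, valleys, peaks, config.confidence_band, config.min_prominence
    )
    dt = 1.0 / fs_hz
    events = []
    for i in range(len(peaks)):
        lo, hi = int(valleys[i]), int(valleys[i + 1])
        pk = int(peaks[i])
        if raw is not None:
            span = np.asarray(raw, dtype=float)[lo : hi + 1]
            force = float(span.max())
            pk = lo + int(np.argmax(span))
        else:
            force = float(sm[pk])
        events.append(
            StrokeEvent(
                peak_index=pk + index_offset,
                peak_force=force,
                start_index=lo + index_offset,
                end_index=hi + index_offset,
                duration=(hi - lo) * dt,
                peak_time=time_offset + pk * dt,
            )
        )
    return events


def stroke_frequency(
    strokes: Sequence[StrokeEvent] | int, ledger: TimeLedger
) -> StrokeRate:
    """Stroke count over treatment time (canonical rate) and contact time."""
    count = strokes if isinstance(strokes, int) else len(strokes)
    if ledger.elapsed_time <= 0:
        raise ValueError("elapsed treatment time is zero")
    treatment = count / ledger.elapsed_time
    contact = count / ledger.contact_time if ledger.contact_time > 0 else 0.0
    return StrokeRate(treatment_rate=treatment, contact_rate=contact)


def segment_bursts(
    strokes: Sequence[StrokeEvent],
    max_gap: float = 2.0,
    freq_tolerance: float = 0.35,
    subsession_ids: Sequence[int] | None = None,
) -> list[Burst]:
    """Greedy split of a stroke train into similar-paced bursts.

    A new burst starts when the inter-stroke interval exceeds ``max_gap``
    seconds, deviates from the running burst mean interval by more than
    ``freq_tolerance`` (fractional), or crosses a sub-session boundary.
    """
    if not strokes:
        return []
    bursts: list[Burst] = []
    cur = [strokes[0]]
    intervals: list[float] = []

    def finalize() -> None:
        if len(cur) > 1:
            span = cur[-1].peak_time - cur[0].peak_time
            freq = (len(cur) - 1) / span if span > 0 else 0.0
        else:
            freq = 0.0
        bursts.append(Burst(strokes=list(cur), mean_frequency=freq))

    for k in range(1, len(strokes)):
        s = strokes[k]
        gap = s.peak_time - strokes[k - 1].peak_time
        crossed = (
            subsession_ids is not None
            and subsession_ids[k] != subsession_ids[k - 1]
        )
        off_pace = bool(intervals) and abs(gap - np.mean(intervals)) > (
            freq_tolerance * np.mean(intervals)
        )
        if crossed or gap > max_gap or off_pace:
            finalize()
            cur = [s]
            intervals = []
        else:
            cur.append(s)
            intervals.append(gap)
    finalize()
    return bursts


def label_burst_pattern(
    burst: Burst,
    f_corrected: np.ndarray,
    euler: np.ndarray,
) -> str:
    """Best-effort force-motion pattern label for a burst.

    Uses the spread of the planar (x-y) force direction and the yaw
    excursion over the burst span: a tight planar direction reads as a
    linear (cross-fiber) pattern, a wide spread with yaw excursion as
    curvilinear (fanning), a wide spread without as hybrid.  Heuristic
    only; not a validated classifier.
    """
    if not burst.strokes:
        return "unknown"
    lo = burst.strokes[0].start_index
    hi = burst.strokes[-1].end_index + 1
    planar = np.asarray(f_corrected, dtype=float)[lo:hi, :2]
    mag = np.linalg.norm(planar, axis=1)
    total = np.linalg.norm(np.asarray(f_corrected, dtype=float)[lo:hi], axis=1)
    if mag.size == 0 or total.max() <= 0 or mag.max() < 0.1 * total.max():
        return "unknown"
    strong = mag > 0.2 * mag.max()
    if not strong.any():
        return "unknown"
    # fold directions into [0, 180): back-and-forth strokes share one axis
    ang = np.degrees(np.arctan2(planar[strong, 1], planar[strong, 0])) % 180.0
    w = mag[strong]
    # circular (period-180) weighted spread
    rad = np.radians(2.0 * ang)
    r = np.hypot(np.average(np.cos(rad), weights=w), np.average(np.sin(rad), weights=w))
    spread = 0.5 * math.degrees(math.sqrt(max(0.0, -2.0 * math.log(max(r, 1e-12)))))
    yaw = np.asarray(euler, dtype=float)[lo:hi, 0]
    yaw_range = float(np.ptp(yaw)) if yaw.size else 0.0
    if spread < 20.0:
        return "linear"
    if yaw_range > 15.0:
        return "curvilinear"
    return "hybrid"
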