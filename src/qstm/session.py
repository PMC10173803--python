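"""Device operating modes, skin-contact classification and time accounting.

The device has an idle mode and a treatment mode; treatment mode walks
through four states: *calibration* (device untouched in its cradle), then
*ready* after a button press, *operational* whenever the resultant force
exceeds the skin-contact threshold (1 N, well above the force noise
floor), and *pause* toggled by further button presses.  Contact time is
the time spent operational; ready plus pause time is the dead time of the
session.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Mode",
    "State",
    "DeviceState",
    "TimeLedger",
    "classify_tick",
    "ledger_update",
    "SessionTracker",
    "track_session",
]

DEFAULT_CONTACT_THRESHOLD = 1.0  # Newtons
DEFAULT_DEBOUNCE = 3  # ticks a force crossing must persist before a switch


class Mode(enum.Enum):
    IDLE = "idle"
    TREATMENT = "treatment"


class State(enum.IntEnum):
    CALIBRATION = 0
    READY = 1
    OPERATIONAL = 2
    PAUSE = 3


@dataclass(frozen=True)
class DeviceState:
    """Operating mode and treatment-mode state of the device."""

    mode: Mode = Mode.TREATMENT
    state: State = State.CALIBRATION
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD


@dataclass(frozen=True)
class TimeLedger:
    """Contact/dead/elapsed time accounting for one treatment session.

    Invariant: ``contact_time + dead_time == elapsed_time`` (elapsed time
    counts treatment-mode ticks after calibration).
    """

    contact_time: float = 0.0
    dead_time: float = 0.0

    @property
    def elapsed_time(self) -> float:
        return self.contact_time + self.dead_time


def classify_tick(
    f_rms: float, button_toggled: bool, state: DeviceState
) -> DeviceState:
    """Classify one output tick of the treatment-mode state machine.

    Pause dominates: a paused device stays paused until the button
    toggles.  Otherwise the device is operational iff the resultant force
    exceeds the contact threshold, else ready.  A button toggle pauses a
    ready/operational device and releases a paused one (to ready, pending
    the force test of the next tick).
    """
    if state.mode is not Mode.TREATMENT:
        raise ValueError("tick classification requires treatment mode")
    s = state.state
    if s is State.CALIBRATION:
        if button_toggled:
            return replace(state, state=State.READY)
        return state
    if s is State.PAUSE:
        if button_toggled:
            return replace(state, state=State.READY)
        return state
    if button_toggled:
        return replace(state, state=State.PAUSE)
    new = State.OPERATIONAL if f_rms > state.contact_threshold else State.READY
    return replace(state, state=new)


def ledger_update(states: np.ndarray, tick_dt: float) -> TimeLedger:
    """Accumulate the time ledger from a per-tick state sequence.

    Calibration ticks are outside the treatment clock and count toward
    neither contact nor dead time.
    """
    s = np.asarray([int(x) for x in states])
    contact = int(np.sum(s == State.OPERATIONAL)) * tick_dt
    dead = int(np.sum((s == State.READY) | (s == State.PAUSE))) * tick_dt
    return TimeLedger(contact_time=contact, dead_time=dead)


class SessionTracker:
    """Stateful tick-by-tick tracker with button edges and force debounce.

    Button presses act on their rising edge.  Ready↔operational switches
    require the force to sit on the other side of the threshold for
    ``debounce`` consecutive ticks, suppressing chatter near 1 N.
    """

    def __init__(
        self,
        contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
        debounce: int = DEFAULT_DEBOUNCE,
    ) -> None:
        self.device = DeviceState(contact_threshold=contact_threshold)
        self.debounce = max(1, int(debounce))
        self._prev_button = False
        self._streak = 0

    def step(self, f_rms: float, button: bool) -> DeviceState:
        toggled = bool(button) and not self._prev_button
        self._prev_button = bool(button)
        current = self.device.state

        if current in (State.CALIBRATION, State.PAUSE) or toggled:
            self.device = classify_tick(f_rms, toggled, self.device)
            self._streak = 0
            return self.device

        # debounced force classification in ready/operational
        proposed = classify_tick(f_rms, False, self.device)
        if proposed.state != current:
            self._streak += 1
            if self._streak >= self.debounce:
                self.device = proposed
                self._streak = 0
        else:
            self._streak = 0
        return self.device


def track_session(
    f_rms: np.ndarray,
    button: np.ndarray,
    dt: float,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    debounce: int = DEFAULT_DEBOUNCE,
) -> tuple[np.ndarray, TimeLedger, list[tuple[int, int]]]:
    """Run the state machine over a session and segment sub-sessions.

    Returns the per-tick :class:`State` codes, the time ledger, and the
    sub-session spans — maximal runs between pause/calibration boundaries
    that contain at least one operational tick, trimmed to their first and
    last operational tick (inclusive index pairs).
    """
    tracker = SessionTracker(contact_threshold, debounce)
    states = np.empty(len(f_rms), dtype=np.int8)
    for i, (f, b) in enumerate(zip(f_rms, button)):
        states[i] = int(tracker.step(float(f), bool(b)).state)

    ledger = ledger_update(states, dt)

    subsessions: list[tuple[int, int]] = []
    in_run = False
    start = 0
    boundary = {int(State.PAUSE), int(State.CALIBRATION)}
    for i, s in enumerate(states):
        if int(s) in boundary:
            if in_run:
                subsessions.append((start, i - 1))
                in_run = False
        elif not in_run:
            in_run = True
            start = i
    if in_run:
        subsessions.append((start, len(states) - 1))

    trimmed = []
    for lo, hi in subsessions:
        ops = np.flatnonzero(states[lo : hi + 1] == int(State.OPERATIONAL))
        if ops.size:
            trimmed.append((lo + int(ops[0]), lo + int(ops[-1])))
    return states, ledger, trimmed
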