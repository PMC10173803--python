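import numpy as np
import pytest

from qstm.pipeline import run_session
from qstm.simulator import SessionScript, StrokeScript, default_calibration, simulate_session


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_subsession_run():
    """A scripted two-sub-session session and its pipeline result.

    Sub-session 1: 8 linear strokes at 2 Hz peaking 25 N; sub-session 2:
    6 fanning strokes at 1 Hz peaking 15 N; 3 s pause in between.
    """
    script = SessionScript(
        subsessions=[
            [StrokeScript(peak_force=25.0, rate=2.0, n_strokes=8)],
            [
                StrokeScript(
                    pattern="fanning_curvilinear",
                    peak_force=15.0,
                    rate=1.0,
                    n_strokes=6,
                )
            ],
        ],
        pause_duration=3.0,
        seed=77,
    )
    stream, truth = simulate_session(script)
    result = run_session(stream, script.cal)
    return script, stream, truth, result
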