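import pytest

from timedseq.config import builtin_stage
from timedseq.engine import Press, run_session


@pytest.fixture(scope="session")
def baseline():
    return builtin_stage("LLRR_baseline")


def midpoint_gaps(cfg):
    """One comfortable gap per transition: the window midpoint, or 1 s on
    effectively untimed transitions."""
    gaps = []
    for w in cfg.windows:
        gaps.append((w.low + w.high) / 2 if w.high - w.low <= 60 else 1.0)
    return gaps


def scripted_stream(cfg, n_trials, start=2.0, intertrial=2.0):
    """Error-free press stream: every trial at window midpoints."""
    presses = []
    t = start
    for _ in range(n_trials):
        seq = cfg.target_sequence
        gaps = midpoint_gaps(cfg)
        presses.append(Press(t, seq[0]))
        for lever, gap in zip(seq[1:], gaps):
            t += gap
            presses.append(Press(t, lever))
        t += intertrial
    return presses


@pytest.fixture()
def perfect_baseline_log(baseline):
    return run_session(baseline, scripted_stream(baseline, 45))
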