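"""Write a session to the decimal log dialect, read it back, classify trials.

Each event is one token: ticks-since-previous-event before the decimal
point (0.01 s ticks), a three-digit event code after it.  The analyzer
rebuilds trials and outcome labels from the events alone.
"""

import dataclasses

from timedseq import builtin_stage, classify_trials, read_log, run_session, write_log
from timedseq.agents import generate_session, preset

cfg = builtin_stage("LLRR_baseline")
params = dataclasses.replace(preset("control_like"), seed=8)
log = run_session(cfg, generate_session(params, cfg), header={"animal": "demo"})

doc = write_log(log)
print("log document starts with:")
for line in doc.splitlines()[:3]:
    print(" ", line[:72], "..." if len(line) > 72 else "")

(back,) = read_log(doc)
assert back.events == log.events
trials = classify_trials(back, cfg)
counts: dict[str, int] = {}
for tr in trials:
    counts[tr.category] = counts.get(tr.category, 0) + 1
print(f"\nround-trip exact: {back.events == log.events}")
print(f"trials: {len(trials)}, outcome labels: {counts}")
print()
print("LLRRP trials earned pellets; labels like R, LL or LLL name the")
print("emitted presses of each failed attempt, a trailing macron marks a")
print("too-slow final press.")
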