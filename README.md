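# timedseq

Software twin of the **timed lever-press sequence task**, a multi-stage
operant paradigm for studying motor learning and cognitive flexibility in
mice. In the task, an animal in a two-lever operant box must emit the
four-press sequence **L-L-R-R** with every interpress interval inside a
predefined window (at baseline: 0.5–5 s for L–L, 0.5–20 s for L–R,
0.5–5 s for R–R) to earn a food pellet. Any wrong-lever press or timing
error resets the sequence and triggers a 5 s time-out; a session ends at
40 rewards or 60 minutes, whichever comes first. After acquisition, probe
stages alter the sequence (every fourth trial shortened to L-L-R) or a
single window (LEFT/RIGHT/MIDDLE raise one lower bound), and a final
extinction session withholds reward.

`timedseq` is for researchers designing or analyzing this kind of
paradigm. It provides:

- **config** — all 15 training/testing stages as validated, serializable
  configurations (timing windows, caps, advancement and exclusion
  criteria), plus a human-editable YAML protocol format;
- **engine** — an event-driven state machine reproducing the box's
  contingencies exactly, on a 0.01 s clock, with closed timing windows;
- **logio** — the one-row-per-session decimal log dialect
  (`<ticks>.<code>` tokens, documented code table) and flat summary files;
- **agents** — parameterized synthetic mice (log-normal interval timing,
  error injection, Poisson time-out pressing, bout/pause renewal process,
  a perseveration axis) including `control_like` / `vpa_like` cohort
  presets;
- **analysis** — every behavioral parameter the paradigm defines: the
  trial-outcome taxonomy (LLRRP, R, LR, LLL, LL, LL̄, LLRR, LLRR̄, LLRL,
  …), press accounting, per-transition interval mean/SD/CV, bout and
  pause durations, cumulative curves, stage-advancement decisions and the
  mean ± 2 SD outlier rule;
- a thin **CLI** (`timedseq simulate | analyze | inspect`).

## Worked example

```python
from timedseq import builtin_stage, run_session, summarize_session
from timedseq.agents import generate_session, preset

cfg = builtin_stage("LLRR_baseline")
log = run_session(cfg, generate_session(preset("perfect"), cfg))
s = summarize_session(log, cfg)
print(s.rewards, s.total_presses, s.category_counts)
```

prints

```
40 160 {'LLRRP': 40}
```

— a noiseless agent completes 40 correct trials (4 presses each, 160
presses total), each labeled LLRRP (correct sequence followed by a
pellet), and the session terminates at the reward cap after ~224 s.
The scripts in `examples/` walk through the other capabilities: boundary
probing of the timing windows, the log dialect round trip with trial
classification, and the directional contrast between the `control_like`
and `vpa_like` presets (fewer time-out presses, longer interpress
intervals, and fewer third-left sequence insertions in the vpa-like
group). Each prints the numbers it computes and one line on what they
mean.

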