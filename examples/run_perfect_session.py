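"""One error-free session on the baseline timed LLRR stage.

A noiseless agent presses L-L-R-R with every interpress interval inside
the stage's windows (0.5-5 s, 0.5-20 s, 0.5-5 s), so the session ends at
the 40-reward cap rather than the 60-minute time cap.
"""

from timedseq import builtin_stage, run_session, summarize_session
from timedseq.agents import generate_session, preset

cfg = builtin_stage("LLRR_baseline")
log = run_session(cfg, generate_session(preset("perfect"), cfg))
s = summarize_session(log, cfg)

print(f"stage            : {cfg.stage_id}")
print(f"rewards          : {s.rewards} (cap {cfg.reward_cap})")
print(f"total presses    : {s.total_presses}")
print(f"incorrect presses: {s.incorrect_presses}")
print(f"session duration : {s.duration_s:.0f} s of {cfg.session_cap_s:.0f} s allowed")
print(f"trial categories : {s.category_counts}")
for name, st in sorted(s.interval_stats.items()):
    print(f"interval {name} : mean {st.mean:.2f} s, cv {st.cv:.2f} (n={st.n})")
print()
print("40 rewards from 160 presses (4 per trial) with zero errors: the")
print("session terminated at the reward cap, and every trial is labeled")
print("LLRRP (correct sequence followed by a pellet).")
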