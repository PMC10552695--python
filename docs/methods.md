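# Methods

## The task model

The package models a two-lever operant box running the timed sequence
paradigm as a deterministic event-driven state machine. A stage is fully
described by a `StageConfig`: a target press sequence over {L, R}, one
closed timing window per transition, a time-out duration, session caps
(rewards, minutes, and for extinction a trial cap), a reinforcement flag,
an optional alternation rule, and an advancement rule. The fifteen
builtin stages cover three habituation sessions, basic operant training
(any press rewarded), untimed sequence acquisition (LR, LLR, LLRR), the
timed stages (baseline 0.5–5 / 0.5–20 / 0.5–5 s; strict 0.5–2 / 0.5–10 /
0.5–2 s), the flexibility probes (alternating 3×LLRR+1×LLR; LEFT, RIGHT
and MIDDLE window shifts), a re-establishment baseline, and extinction.
Untimed transitions carry the sentinel window [0.05 s, 3600 s] — the
acquisition-software scale for "no limit" — rather than literal infinity,
so every transition is handled uniformly.

### Contingency semantics

- **Clock.** All times are quantized to 0.01 s ticks at ingest; windows
  and the time-out are compared in integer ticks, so boundary behavior is
  exact and platform independent.
- **Closed windows.** An interval exactly equal to a printed bound is
  correct; one tick outside is an error. This makes the published bounds
  themselves legal and directly testable.
- **Press roles.** A press is `correct`, `incorrect` (wrong lever —
  checked before timing), `too_fast`, `too_slow`, or `timeout` (emitted
  during a lockout). Any error resets the sequence to position 0 and
  starts a 5 s time-out. The first press of a trial — at session start,
  after a reward, or after time-out expiry — is never timing-checked,
  having no predecessor.
- **Lateness at press time.** A window overrun becomes an error only when
  the late press arrives; the log dialect records presses and deliveries,
  not silent deadline expiries. A trial with no further presses never
  completes.
- **Time-outs.** Presses during a lockout are tallied per lever but
  neither advance the sequence nor extend the lockout, which always ends
  exactly `timeout_s` after the error.
- **Alternation.** The alternating stage's schedule is indexed by
  *completed* trials, so a perfect session yields exactly 30 four-press
  and 10 three-press rewarded trials. A habitual fourth press after a
  shortened trial's reward is evaluated under the next trial's
  contingency (an incorrect right first press) and surfaces in the
  analysis as a post-reward right start.
- **Termination.** A session ends at the reward cap, the trial cap
  (extinction keeps the 40-trial maximum mirroring the reward cap), or
  the time cap, whichever is reached first; the session-end event carries
  that time.
- **Cue lights.** Cue on/off events bracket exactly the period a lever is
  armed (both levers during any-lever training, none during time-outs).
  They are derivable from the contingencies, and analyzers may ignore
  them.

## Log dialect

One row per session; each event is `<ticks>.<3-digit code>`, the integer
part counting 0.01 s ticks since the previous event. The code table is
this package's own documented dialect (the field's acquisition software
uses task-specific assignments that are not standardized): press codes
encode role × lever (tens digit = role, units = lever), with additional
codes for reward, pellet preload, trial completion, time-out
onset/offset, cue transitions, and session markers. A `trial_complete`
code is recorded so that completed sequences are parseable on extinction,
where no reward event follows. Headers (`# key: value`) precede each row.
Reading reconstructs absolute times as prefix sums; unknown codes are
kept and reported, malformed tokens fail with row and column. Writing is
bit-stable, and write∘read is the identity.

## Synthetic agents

Agents are stationary per-stage policies intended to exercise every
engine and analysis path at desk scale, not to model learning
mechanistically. Within-stage acquisition is deliberately absent; the
paradigm's published group contrasts concern stage-wise performance, and
stationary policies keep parameter recovery well defined.

- **Timing** on each transition is log-normal (positive, right-skewed
  interresponse times), median `exp(interval_mu)`, spread
  `interval_sigma`; σ = 0 collapses to the median (the `perfect` preset).
- **Adaptation vs perseveration.** On every transition the agent samples
  from its trained policy with probability `perseveration`, otherwise
  from a window-adapted policy whose median is the trained median clipped
  into [1.15·low, 0.85·high] of the current window. This single mixture
  is the minimal mechanism producing both timing-probe adaptation and
  sequence-habit effects.
- **Errors.** Wrong-lever presses (`lever_confusion_p`) and deliberate
  premature/late presses (`premature_p`, `late_p`; late injection is
  skipped on effectively untimed transitions). Additionally, a
  **bridging press**: while waiting out a gap more than twice the trained
  median on a lever-change transition, error-prone agents re-press the
  previous lever with probability 0.5·(1 − perseveration). This is what
  produces extra third-left presses in the MIDDLE probe, and it is why
  less perseverative (control-like) agents restructure the sequence more.
- **Time-out pressing** is Poisson at `timeout_press_rate` per second,
  strictly inside the lockout, on a uniformly random lever.
- **Activity structure** is a two-state renewal process: exponential bout
  lengths (`bout_mean_s`) and pause lengths (`pause_mean_s`), plus an
  extra per-trial-boundary pause probability `pause_p`. It exists to
  exercise the bout/pause analyzer.
- **Reward omission.** On unreinforced stages the sampled final-transition
  interval is stretched by (1 + 0.35·perseveration): perseverative
  animals respond to omission by slowing the terminal press rather than
  restarting.

The agent co-simulates the contingencies with its own engine instance
while generating, so its reactions are exactly consistent with what the
engine decides when the stream is replayed; the emitted stream is an
ordinary open-loop press list.

### Presets

`control_like` and `vpa_like` share all parameters except three
documented directions: trained medians 1.2/1.2/0.9 s vs 1.5/1.5/1.15 s
(the reward-proximal R–R transition faster in both), time-out press rate
0.8 vs 0.35 s⁻¹, perseveration 0.15 vs 0.45. Magnitudes are free
parameters chosen once to give plausible session statistics (several
hundred presses, mostly-successful baseline sessions); only the signs of
the group contrasts are claimed. `perfect` is noiseless; `random` picks
levers uniformly with uninformative timing.

What the generator does **not** emulate: within-session learning or
satiety, motivation drift, reward-consumption interruptions of bouts,
side biases, and any mechanistic account of timing (no pacemaker or
reinforcement-learning model). Passing tests therefore demonstrate that
the contingencies, log format, and analyses are correct and internally
consistent — not that real mice behave like the agents.

## Analysis conventions

- **Trials.** A trial starts at the first non-time-out press after
  session start, reward, or time-out expiry, and ends with an error press
  or a completing press; time-out presses belong to no trial. Outcome
  labels follow the display convention: emitted letters, trailing "P" for
  a completed sequence, a combining macron on the final letter for a
  too-slow last press. The canonical machine form appends the failure
  mode and position (`LL_slow2`). On LLRR stages this reproduces the
  familiar nine-label taxonomy and extends it with the two third-press
  timing labels (`LLR`, `LLR̄`) the physics of the task admits.
- **Integrity.** Analyses replay the logged presses through the engine
  and require the recomputed event stream to match the log exactly; the
  first divergent event is reported. The engine's internal tallies and
  the analyzer's recomputation are two independent routes whose equality
  is asserted across a corpus of random sessions on all stages.
- **Intervals** are collected from correctly executed sequences only,
  keyed by transition (`1:L-L`, `2:L-R`, `3:R-R`); SD uses the sample
  (n − 1) denominator and CV = SD/mean. With fewer than two intervals SD
  and CV are 0.
- **Bouts/pauses.** A pause is any interpress gap ≥ the threshold
  (default 30 s — the paradigm reports bout/pause durations without
  publishing its split, so the threshold is an explicit, configurable
  parameter); bouts are the complementary maximal press runs, the
  partition starting at the first press. All presses, including time-out
  presses, count as activity.
- **Advancement.** Criterion stages require N consecutive successful
  sessions (40 rewards); at the session cap an animal is excluded unless
  the stage defines a minimum-trials rescue (timed stages: ≥ 10 attempted
  trials on the 10th session forces advancement). Probe stages run a
  fixed count with no exclusion. Habituation consumption is not an
  observable log event, so simulated habituation sessions are taken as
  criterion-passing.
- **Outliers.** Values strictly outside mean ± 2·SD (sample SD) are
  flagged in a single pass; the rule is deliberately not iterated, so it
  is not idempotent on its own output.

## Numerical and scale choices

Problem sizes used by the test suite and the acceptance script are those
the paradigm itself fixes: 40-reward sessions, 15 scheduled habituation
deliveries, 0.01 s grid probes of the window edges and the 5 s lockout,
and cohorts of 11 per group for the directional preset contrasts (a
single first timed session and a single MIDDLE probe session per animal,
with fixed seeds). The property corpus covers all 15 stages with 7
sessions each across three noisy presets. Parameter recovery is checked
on ≥ 200 correct trials against the log-normal's closed-form mean
exp(μ + σ²/2) and CV √(exp(σ²) − 1), within 3 Monte-Carlo standard
errors.

## Known limitations

- Agents have no within-stage learning; between-stage change is limited
  to the perseveration mixture.
- The event-code assignments are this package's own dialect; files from
  other acquisition systems need code-table translation before parsing.
- Group-level inferential statistics (t tests, ANOVA) are intentionally
  out of scope: the analysis layer exports per-animal, per-session
  parameter tables for external statistical software.
- The habituation consumption criterion cannot be evaluated from logs and
  is assumed satisfied in simulation.
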