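protocol:
- stage: habituation1
  target_sequence: ''
  windows: []
  timeout_s: 0.0
  session_cap_min: 10.0
  reward_cap: 1
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: none, fixed_sessions: 1}
- stage: habituation2
  target_sequence: ''
  windows: []
  timeout_s: 0.0
  session_cap_min: 10.0
  reward_cap: 4
  reinforced: true
  any_lever: false
  manual_preload: 4
  criteria: {criterion: consume, max_sessions: 10}
- stage: habituation3
  target_sequence: ''
  windows: []
  timeout_s: 0.0
  session_cap_min: 30.0
  reward_cap: 15
  reinforced: true
  any_lever: false
  manual_preload: 0
  scheduled_delivery_s: 120.0
  criteria: {criterion: consume, max_sessions: 10}
- stage: operant_training
  target_sequence: L
  windows: []
  timeout_s: 0.0
  session_cap_min: 30.0
  reward_cap: 40
  reinforced: true
  any_lever: true
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, max_sessions: 10}
- stage: LR
  target_sequence: LR
  windows:
  - [0.05, 3600.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, consecutive_days: 3, max_sessions: 10}
- stage: LLR
  target_sequence: LLR
  windows:
  - [0.05, 3600.0]
  - [0.05, 3600.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, consecutive_days: 3, max_sessions: 10}
- stage: LLRR
  target_sequence: LLRR
  windows:
  - [0.05, 3600.0]
  - [0.05, 3600.0]
  - [0.05, 3600.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, consecutive_days: 3, max_sessions: 10}
- stage: LLRR_baseline
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [0.5, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, consecutive_days: 3, max_sessions: 10,
    last_session_min_trials: 10}
- stage: LLRR_strict
  target_sequence: LLRR
  windows:
  - [0.5, 2.0]
  - [0.5, 10.0]
  - [0.5, 2.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, consecutive_days: 3, max_sessions: 10,
    last_session_min_trials: 10}
- stage: LLRR_alternating
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [0.5, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  alternation: {period: 4, alternate_sequence: LLR}
  criteria: {criterion: none, fixed_sessions: 3}
- stage: LLRR_rebaseline
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [0.5, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: rewards, required_rewards: 40, max_sessions: 3, last_session_min_trials: 10}
- stage: LLRR_left
  target_sequence: LLRR
  windows:
  - [1.5, 5.0]
  - [0.5, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: none, fixed_sessions: 3}
- stage: LLRR_right
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [0.5, 20.0]
  - [1.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: none, fixed_sessions: 3}
- stage: LLRR_middle
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [3.0, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: true
  any_lever: false
  manual_preload: 0
  criteria: {criterion: none, fixed_sessions: 3}
- stage: Extinction
  target_sequence: LLRR
  windows:
  - [0.5, 5.0]
  - [0.5, 20.0]
  - [0.5, 5.0]
  timeout_s: 5.0
  session_cap_min: 60.0
  reward_cap: 40
  reinforced: false
  any_lever: false
  manual_preload: 0
  trial_cap: 40
  criteria: {criterion: none, fixed_sessions: 1}
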