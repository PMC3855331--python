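{
  "option_labels": [
    "A",
    "B",
    "C",
    "D"
  ],
  "reward_pellets": [
    2,
    2,
    1,
    1
  ],
  "timeout_seconds": [
    444.0,
    222.0,
    12.0,
    6.0
  ],
  "penalty_prob": [
    0.5,
    0.25,
    0.25,
    0.5
  ],
  "penalty_pellets": [
    -50.0,
    -25.0,
    -1.3333333333333333,
    -0.6666666666666666
  ],
  "episode_seconds": 9.0,
  "session_seconds": 3600.0,
  "pellet_cap": 250,
  "forced_exploration_seconds": 600.0,
  "bin_seconds": 600.0,
  "advantageous_set": [
    "C",
    "D"
  ],
  "hole_to_option": [
    0,
    1,
    2,
    3
  ]
}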