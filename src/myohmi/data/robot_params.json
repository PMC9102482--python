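{
  "comment": "Default 3-DOF anthropomorphic arm: desk-scale links chosen so every state set-point is reachable.",
  "l": [0.30, 0.25, 0.25],
  "lc": [0.15, 0.125, 0.125],
  "m": [1.0, 1.0, 0.8],
  "I": [0.01, 0.01, 0.01],
  "B": [0.1, 0.1, 0.1],
  "g": 9.81,
  "gains": {"Kp": [100.0, 100.0, 100.0], "Kv": [20.0, 20.0, 20.0]}
}
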