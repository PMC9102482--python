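{
  "version": 1,
  "comment": "Mealy transitions by contraction class. SMP stops, SMP3 moves on the vertical/diagonal axis (twice from a diagonal reaches the down diagonals), SMP5 cycles horizontally. NIM deactivates from every state (HOME).",
  "transitions": {
    "S1":  {"SMP": "S1", "SMP3": "S2",  "SMP5": "S3",  "NIM": "HOME"},
    "S2":  {"SMP": "S1", "SMP3": "S1",  "SMP5": "DUR", "NIM": "HOME"},
    "S3":  {"SMP": "S1", "SMP3": "DUR", "SMP5": "S4",  "NIM": "HOME"},
    "S4":  {"SMP": "S1", "SMP3": "DUL", "SMP5": "S1",  "NIM": "HOME"},
    "DUR": {"SMP": "S1", "SMP3": "DDR", "SMP5": "DUL", "NIM": "HOME"},
    "DUL": {"SMP": "S1", "SMP3": "DDL", "SMP5": "S2",  "NIM": "HOME"},
    "DDR": {"SMP": "S1", "SMP3": "S3",  "SMP5": "DDL", "NIM": "HOME"},
    "DDL": {"SMP": "S1", "SMP3": "S4",  "SMP5": "S1",  "NIM": "HOME"}
  }
}
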