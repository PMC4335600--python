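{
  "fsrs": {
    "male": {"5": 13.0, "10": 32.0},
    "female": {"5": 19.5, "10": 42.0}
  },
  "riskometer": {
    "male": {"5": 21.5, "10": 43.0},
    "female": {"5": 22.0, "10": 45.0}
  },
  "qstroke": {
    "male": {"5": 8.6, "10": 22.0},
    "female": {"5": 23.0, "10": 48.0}
  }
}
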