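{
  "comment": "Per-residue coiled-coil propensities (ratio to background) for heptad core (a/d) and non-core (b,c,e,f,g) positions. Scores are natural-log ratios of these values.",
  "ad": {
    "L": 3.2, "I": 3.0, "M": 2.5, "V": 2.3, "F": 2.0, "A": 1.6,
    "Y": 0.9, "W": 0.8, "C": 0.8, "Q": 0.6, "E": 0.5, "K": 0.5,
    "R": 0.5, "H": 0.5, "T": 0.45, "S": 0.45, "N": 0.45, "D": 0.35,
    "G": 0.25, "P": 0.05
  },
  "other": {
    "A": 1.1, "L": 0.9, "I": 0.8, "V": 0.8, "M": 0.9, "F": 0.8,
    "W": 0.8, "Y": 0.9, "C": 0.7, "G": 0.6, "P": 0.15, "E": 1.3,
    "K": 1.25, "Q": 1.2, "R": 1.1, "D": 1.1, "N": 1.05, "S": 1.0,
    "T": 1.0, "H": 1.0
  }
}
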