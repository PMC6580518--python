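{
  "comment": "SYNTHETIC position-weight profile for the Hsf DNA-binding domain (helix-turn-helix-like fold with a beta-sheet cap). The consensus is an invented, composition-plausible stand-in constructed in-package; it is not derived from any deposited alignment. The synthetic genome generator plants instances of this same profile, keeping recovery tests closed-world.",
  "consensus": "MKEGSNQAPFLVKTYDIVEDSSTNHIVSWGRGNNSFVVLDPREFSRDLLPAHFKHNNFSSFIRELNSYGWHKVQPDRWEFSNEWFQRGEKHLLS",
  "match_prob": 0.75,
  "background_prob": 0.05
}
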