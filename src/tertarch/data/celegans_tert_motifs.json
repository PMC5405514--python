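{
  "reference_id": "CeTERT",
  "reference_length": 514,
  "description": "Approximate literature-derived residue intervals (0-based, half-open) for C. elegans TERT (TRT-1), one of the shortest known TERTs; it lacks a C-terminal extension. These packaged coordinates are a convenience fixture, not an authoritative annotation; override with your own JSON config for exact work.",
  "motifs": {
    "GQ": [10, 90],
    "CP": [120, 150],
    "QFP": [170, 220],
    "T": [225, 260],
    "1": [270, 290],
    "2": [295, 315],
    "A": [340, 360],
    "Bprime": [400, 425],
    "C": [430, 450],
    "D": [460, 480],
    "E": [485, 505]
  }
}
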