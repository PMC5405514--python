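{
  "reference_id": "hTERT",
  "reference_length": 1132,
  "description": "Approximate literature-derived residue intervals (0-based, half-open) for the canonical human TERT motifs. These packaged coordinates are a convenience fixture, not an authoritative annotation; override with your own JSON config for exact work. DAT nests inside GQ; the linker (GQ end to CP start) and CTE (E end to C terminus) are derived regions.",
  "motifs": {
    "GQ": [0, 195],
    "DAT": [90, 130],
    "CP": [407, 450],
    "QFP": [497, 560],
    "T": [560, 600],
    "1": [614, 640],
    "2": [647, 665],
    "A": [704, 725],
    "Bprime": [824, 850],
    "C": [857, 882],
    "D": [893, 917],
    "E": [918, 940]
  }
}
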