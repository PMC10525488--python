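{
  "layout_id": "deap32",
  "regions": {
    "R1": ["Fp1", "Fp2", "AF3", "AF4"],
    "R2": ["F7", "F3", "Fz", "F4", "F8"],
    "R3": ["FC5", "T7", "CP5"],
    "R4": ["FC6", "T8", "CP6"],
    "R5": ["FC1", "C3", "Cz", "C4", "FC2"],
    "R6": ["P3", "P7", "PO3"],
    "R7": ["CP1", "Pz", "CP2"],
    "R8": ["P8", "P4", "PO4"],
    "R9": ["O1", "Oz", "O2"]
  }
}
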