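{
  "comment": "Bjellqvist pKa set as used by the ExPASy Compute pI/Mw service",
  "c_terminus": 3.55,
  "n_terminus_default": 7.5,
  "n_terminus": {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7
  },
  "sidechain_acidic": {
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0
  },
  "sidechain_basic": {
    "H": 5.98, "K": 10.0, "R": 12.0
  }
}
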