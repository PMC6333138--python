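{
  "comment": "Organ-specific dose-to-CTDIvol coefficients for a 70 kg adult.",
  "lung": {
    "120": {"f_organ": 1.50, "f_sigma": 0.06}
  }
}
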