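{
  "phantom_id": "adult_rando",
  "organs": [
    {
      "organ": "lung",
      "rows": [
        {"slice": 11, "f": 0.06, "n_groups": 2},
        {"slice": 12, "f": 0.09, "n_groups": 2},
        {"slice": 13, "f": 0.11, "n_groups": 6},
        {"slice": 14, "f": 0.14, "n_groups": 6},
        {"slice": 15, "f": 0.14, "n_groups": 8},
        {"slice": 16, "f": 0.13, "n_groups": 6},
        {"slice": 17, "f": 0.13, "n_groups": 4},
        {"slice": 18, "f": 0.11, "n_groups": 4},
        {"slice": 19, "f": 0.09, "n_groups": 2}
      ]
    }
  ]
}
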