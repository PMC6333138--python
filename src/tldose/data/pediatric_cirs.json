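{
  "phantom_id": "pediatric_cirs",
  "organs": [
    {
      "organ": "thyroid",
      "rows": [
        {"slice": 8, "f": 1.00, "n_groups": 4}
      ]
    },
    {
      "organ": "lung",
      "rows": [
        {"slice": 9, "f": 0.02, "n_groups": 2},
        {"slice": 10, "f": 0.14, "n_groups": 4},
        {"slice": 11, "f": 0.19, "n_groups": 6},
        {"slice": 12, "f": 0.22, "n_groups": 6},
        {"slice": 13, "f": 0.23, "n_groups": 8},
        {"slice": 14, "f": 0.17, "n_groups": 4},
        {"slice": 15, "f": 0.03, "n_groups": 2}
      ]
    }
  ]
}
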