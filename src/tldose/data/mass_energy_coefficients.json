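{
  "comment": "Mass-energy absorption coefficients (cm^2/g) per tube voltage; air is at sea level.",
  "120": {
    "air": 0.0339,
    "lung": 0.0365,
    "thyroid": 0.0402
  },
  "80": {
    "air": 0.0521,
    "lung": 0.0557,
    "thyroid": 0.0610
  }
}
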