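{
  "phantom_id": "pediatric_cirs",
  "scanner": "Philips Brilliance 64",
  "protocols": [
    {
      "name": "PED120",
      "tube_voltage": 120,
      "tube_current": 121,
      "rotation_time": 0.45,
      "pitch": 0.922,
      "collimation": "64x0.625",
      "ctdi_vol": 3.7,
      "dlp": 103.6,
      "tcm_mode": "none"
    },
    {
      "name": "PED80",
      "tube_voltage": 80,
      "tube_current": 323,
      "rotation_time": 0.45,
      "pitch": 0.922,
      "collimation": "64x0.625",
      "ctdi_vol": 2.8,
      "dlp": 76.4,
      "tcm_mode": "none"
    },
    {
      "name": "PED120TCM",
      "tube_voltage": 120,
      "tube_current": [66, 118],
      "rotation_time": 0.45,
      "pitch": 0.922,
      "collimation": "64x0.625",
      "ctdi_vol": 2.8,
      "dlp": 85.0,
      "tcm_mode": "longitudinal"
    },
    {
      "name": "PED80TCM",
      "tube_voltage": 80,
      "tube_current": [168, 318],
      "rotation_time": 0.45,
      "pitch": 0.922,
      "collimation": "64x0.625",
      "ctdi_vol": 2.2,
      "dlp": 65.3,
      "tcm_mode": "longitudinal"
    }
  ]
}
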