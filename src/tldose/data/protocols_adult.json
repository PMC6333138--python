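{
  "phantom_id": "adult_rando",
  "scanner": "GE Discovery CT750 HD",
  "protocols": [
    {
      "name": "SPR",
      "tube_voltage": 120,
      "tube_current": 10,
      "rotation_time": null,
      "pitch": null,
      "collimation": null,
      "ctdi_vol": null,
      "dlp": null,
      "tcm_mode": "none"
    },
    {
      "name": "STD",
      "tube_voltage": 120,
      "tube_current": 300,
      "rotation_time": 0.6,
      "pitch": 1.375,
      "collimation": "64x0.625",
      "ctdi_vol": 10.03,
      "dlp": 465.90,
      "tcm_mode": "none"
    },
    {
      "name": "LD",
      "tube_voltage": 120,
      "tube_current": 120,
      "rotation_time": 0.4,
      "pitch": 1.375,
      "collimation": "64x0.625",
      "ctdi_vol": 2.76,
      "dlp": 128.52,
      "tcm_mode": "none"
    },
    {
      "name": "ULD",
      "tube_voltage": 120,
      "tube_current": 40,
      "rotation_time": 0.4,
      "pitch": 1.375,
      "collimation": "64x0.625",
      "ctdi_vol": 0.92,
      "dlp": 42.81,
      "tcm_mode": "none"
    },
    {
      "name": "AutomA",
      "tube_voltage": 120,
      "tube_current": [80, 300],
      "rotation_time": 0.6,
      "pitch": 1.375,
      "collimation": "64x0.625",
      "ctdi_vol": 6.61,
      "dlp": 306.96,
      "tcm_mode": "longitudinal"
    },
    {
      "name": "AutoSmartmA",
      "tube_voltage": 120,
      "tube_current": [80, 300],
      "rotation_time": 0.6,
      "pitch": 1.375,
      "collimation": "64x0.625",
      "ctdi_vol": 5.59,
      "dlp": 259.49,
      "tcm_mode": "longitudinal+angular"
    }
  ]
}
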