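protocol,organ,dose_mGy,sigma_mGy,mAs_printed
PED120,thyroid,6.84,0.25,55
PED80,thyroid,5.93,0.31,146
PED120TCM,thyroid,4.05,0.25,
PED80TCM,thyroid,3.02,0.13,
PED120,lung,6.12,0.27,55
PED80,lung,4.58,0.22,146
PED120TCM,lung,5.13,0.23,
PED80TCM,lung,3.66,0.16,
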