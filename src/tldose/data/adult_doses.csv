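protocol,organ,dose_mGy,sigma_mGy,sim_mGy
SPR,lung,0.19,0.01,
STD,lung,14.30,0.72,13.24
LD,lung,3.88,0.19,3.64
ULD,lung,1.24,0.06,1.21
AutomA,lung,11.90,0.60,14.11
AutoSmartmA,lung,9.29,0.46,11.23
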