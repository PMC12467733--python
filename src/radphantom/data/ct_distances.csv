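pair,plane,distance_mm
C-LH,1,543.17
C-RH,1,602.95
LH-RH,1,172.42
RS-LP,2,536.14
LS-RP,2,542.83
RS-RP,2,463.26
LS-RS,2,275.69
LS-LP,2,463.30
LP-RP,2,277.23
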