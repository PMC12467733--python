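system,plane,label,diameter_mm
Eagle Eye,1,C,9.69
Eagle Eye,1,LH,9.64
Eagle Eye,1,RH,9.75
Eagle Eye,2,RP,9.59
Eagle Eye,2,LP,9.64
Eagle Eye,2,LS,9.58
Eagle Eye,2,RS,9.53
EOS,1,C,7.92
EOS,1,LH,7.96
EOS,1,RH,8.01
EOS,2,RP,7.88
EOS,2,LP,7.88
EOS,2,LS,7.85
EOS,2,RS,7.82
GC85A,1,C,9.14
GC85A,1,LH,9.30
GC85A,1,RH,9.30
GC85A,2,RP,8.74
GC85A,2,LP,8.70
GC85A,2,LS,8.47
GC85A,2,RS,8.44
UDR780IPRO3F,1,C,9.93
UDR780IPRO3F,1,LH,10.04
UDR780IPRO3F,1,RH,10.13
UDR780IPRO3F,2,RP,9.72
UDR780IPRO3F,2,LP,9.51
UDR780IPRO3F,2,LS,9.45
UDR780IPRO3F,2,RS,9.41
DRX-Compass,1,C,11.92
DRX-Compass,1,LH,11.84
DRX-Compass,1,RH,11.94
DRX-Compass,2,RP,11.75
DRX-Compass,2,LP,11.79
DRX-Compass,2,LS,11.29
DRX-Compass,2,RS,11.27
DSI-DRP,1,C,8.67
DSI-DRP,1,LH,8.76
DSI-DRP,1,RH,8.65
DSI-DRP,2,RP,8.57
DSI-DRP,2,LP,8.53
DSI-DRP,2,LS,8.50
DSI-DRP,2,RS,8.60
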