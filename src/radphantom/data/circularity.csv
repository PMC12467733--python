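system,label,metric
Eagle Eye,RS,0.68
Eagle Eye,RP,0.56
Eagle Eye,RH,0.58
Eagle Eye,LS,0.57
Eagle Eye,LP,0.65
Eagle Eye,LH,0.54
Eagle Eye,C,0.64
EOS,RS,0.60
EOS,RP,0.69
EOS,RH,0.61
EOS,LS,0.60
EOS,LP,0.59
EOS,LH,0.46
EOS,C,0.74
UDR780IPRO3F,RS,0.61
UDR780IPRO3F,RP,0.56
UDR780IPRO3F,RH,0.46
UDR780IPRO3F,LS,0.52
UDR780IPRO3F,LP,0.54
UDR780IPRO3F,LH,0.53
UDR780IPRO3F,C,0.53
GC85A,RS,0.63
GC85A,RP,0.53
GC85A,RH,0.52
GC85A,LS,0.61
GC85A,LP,0.56
GC85A,LH,0.53
GC85A,C,0.77
DRX-Compass,RS,0.48
DRX-Compass,RP,0.29
DRX-Compass,RH,0.21
DRX-Compass,LS,0.50
DRX-Compass,LP,0.26
DRX-Compass,LH,0.28
DRX-Compass,C,0.48
DSI-DRP,RS,0.54
DSI-DRP,RP,0.61
DSI-DRP,RH,0.62
DSI-DRP,LS,0.59
DSI-DRP,LP,0.54
DSI-DRP,LH,0.60
DSI-DRP,C,0.71
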