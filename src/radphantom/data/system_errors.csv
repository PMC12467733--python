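system,method,pair,plane,error_mm
Eagle Eye,slot,RS-LP,2,0.77
Eagle Eye,slot,LS-RP,2,-8.81
Eagle Eye,slot,RS-RP,2,-10.42
Eagle Eye,slot,LS-RS,2,-11.03
Eagle Eye,slot,LS-LP,2,4.29
Eagle Eye,slot,LP-RP,2,6.08
Eagle Eye,slot,C-LH,1,-12.43
Eagle Eye,slot,C-RH,1,-2.70
Eagle Eye,slot,LH-RH,1,15.97
EOS,slot,RS-LP,2,3.80
EOS,slot,LS-RP,2,-7.76
EOS,slot,RS-RP,2,-8.56
EOS,slot,LS-RS,2,-15.02
EOS,slot,LS-LP,2,7.49
EOS,slot,LP-RP,2,9.92
EOS,slot,C-LH,1,-9.63
EOS,slot,C-RH,1,-2.41
EOS,slot,LH-RH,1,19.08
UDR780IPRO3F,rotational,RS-LP,2,-19.65
UDR780IPRO3F,rotational,LS-RP,2,-23.63
UDR780IPRO3F,rotational,RS-RP,2,-22.00
UDR780IPRO3F,rotational,LS-RS,2,-15.58
UDR780IPRO3F,rotational,LS-LP,2,-18.66
UDR780IPRO3F,rotational,LP-RP,2,-0.54
UDR780IPRO3F,rotational,C-LH,1,-40.67
UDR780IPRO3F,rotational,C-RH,1,-38.59
UDR780IPRO3F,rotational,LH-RH,1,-1.88
GC85A,rotational,RS-LP,2,-22.46
GC85A,rotational,LS-RP,2,-24.54
GC85A,rotational,RS-RP,2,-24.06
GC85A,rotational,LS-RS,2,-16.94
GC85A,rotational,LS-LP,2,-18.54
GC85A,rotational,LP-RP,2,-3.17
GC85A,rotational,C-LH,1,-33.73
GC85A,rotational,C-RH,1,-32.18
GC85A,rotational,LH-RH,1,-2.39
DRX-Compass,rotational,RS-LP,2,-38.79
DRX-Compass,rotational,LS-RP,2,-27.10
DRX-Compass,rotational,RS-RP,2,-19.89
DRX-Compass,rotational,LS-RS,2,-30.94
DRX-Compass,rotational,LS-LP,2,-34.79
DRX-Compass,rotational,LP-RP,2,-4.84
DRX-Compass,rotational,C-LH,1,-2.69
DRX-Compass,rotational,C-RH,1,-3.69
DRX-Compass,rotational,LH-RH,1,10.37
DSI-DRP,one_shot,RS-LP,2,-11.87
DSI-DRP,one_shot,LS-RP,2,-9.65
DSI-DRP,one_shot,RS-RP,2,-4.48
DSI-DRP,one_shot,LS-RS,2,-4.24
DSI-DRP,one_shot,LS-LP,2,-13.61
DSI-DRP,one_shot,LP-RP,2,-8.86
DSI-DRP,one_shot,C-LH,1,-35.93
DSI-DRP,one_shot,C-RH,1,-36.86
DSI-DRP,one_shot,LH-RH,1,-12.42
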