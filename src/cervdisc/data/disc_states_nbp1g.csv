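level,h_mm,A_mm2,V_printed_mm3,phi_np,phi_af
C2C3,3.1,380,1178,0.80,0.75
C3C4,3.51,420,1474.2,0.82,0.76
C4C5,4.12,490,2018.8,0.81,0.76
C5C6,5.01,530,2655.3,0.83,0.78
C6C7,4.2,540,2268,0.82,0.77
C7T1,3.7,370,1369,0.81,0.76
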