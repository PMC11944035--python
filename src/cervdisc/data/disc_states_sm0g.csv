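level,h_mm,A_mm2,V_printed_mm3,phi_np,phi_af
C2C3,3.13,390,1220.7,0.85,0.77
C3C4,3.56,440,1566.4,0.866,0.788
C4C5,4.2,512,2150.4,0.868,0.789
C5C6,5.2,542,2814.4,0.85,0.788
C6C7,4.27,570,2433.9,0.83,0.78
C7T1,3.75,390,1462.5,0.835,0.762
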