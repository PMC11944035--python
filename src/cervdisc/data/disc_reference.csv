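level,A0_mm2,h0_mm,phi0_np,phi0_af
C2C3,380,3.1,0.8,0.75
C3C4,420,3.51,0.8,0.75
C4C5,490,4.12,0.8,0.75
C5C6,530,5.01,0.8,0.75
C6C7,540,4.2,0.8,0.75
C7T1,370,3.7,0.8,0.75
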