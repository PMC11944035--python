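level,h_mm,A_mm2,V_printed_mm3,phi_np,phi_af
C2C3,3.15,392,1234.8,0.87,0.783
C3C4,3.6,442,1591.2,0.87,0.79
C4C5,4.21,515,2168.15,0.874,0.79
C5C6,5.25,547,2871.75,0.86,0.79
C6C7,4.28,577,2469.56,0.835,0.79
C7T1,3.8,394,1497.2,0.841,0.767
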