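level,compression_N,shear_N
C2C3,21.5,-5.3
C3C4,25.77,-4.02
C4C5,27.9,-1.05
C5C6,30.5,-0.3
C6C7,35.2,1.9
C7T1,40.7,3.7
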