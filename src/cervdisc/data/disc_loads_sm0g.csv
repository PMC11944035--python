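level,compression_N,shear_N
C2C3,22.11,-4.3
C3C4,24.98,-4.43
C4C5,27.17,-1.53
C5C6,28.92,-1.06
C6C7,33.37,0.09
C7T1,39.37,0.29
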