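level,compression_N,shear_N
C2C3,91.83,-13.27
C3C4,101.69,-15.44
C4C5,110.37,-11.29
C5C6,121.15,-12.61
C6C7,144.87,-10.67
C7T1,178.07,-7.9
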