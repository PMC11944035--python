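scenario,ligament,force_N
nbp1g,ALL,38.46
nbp1g,PLL,59.95
nbp1g,LF,41.86
sm0g,ALL,95.02
sm0g,PLL,174.21
sm0g,LF,89.37
nbp0g,ALL,92.76
nbp0g,PLL,183.26
nbp0g,LF,85.97
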