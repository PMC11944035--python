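ligament,region,stiffness_N_per_mm,strain_lo_pct,strain_hi_pct,slack_strain_pct,reference_length_mm
ALL,C2C5,16,25.8,35.8,0,20
ALL,C5T1,17.9,29.54,41.26,0,20
PLL,C2C5,25.4,14.99,21.41,0,20
PLL,C5T1,23,25.33,42.87,0,20
LF,C2C5,25,64.1,89.9,0,20
LF,C5T1,21.6,75.3,101.5,0,20
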