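# name=adipose
# density_g_per_cm3=0.95
energy_kev,mass_atten_cm2_per_g
10,3.314
15,1.087
20,0.575
30,0.3046
40,0.2396
50,0.2123
60,0.1974
80,0.1805
100,0.1694
150,0.1506
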