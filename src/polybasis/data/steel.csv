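# name=steel
# density_g_per_cm3=7.87
energy_kev,mass_atten_cm2_per_g
10,170.6
15,57.08
20,25.68
30,8.176
40,3.629
50,1.958
60,1.205
80,0.5952
100,0.3717
150,0.1964
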