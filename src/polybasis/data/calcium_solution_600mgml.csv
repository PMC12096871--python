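# name=calcium_solution_600mgml
# density_g_per_cm3=1.43
energy_kev,mass_atten_cm2_per_g
10,42.2861
15,13.399
20,5.83634
30,1.88332
40,0.90216
50,0.551697
60,0.395508
80,0.260022
100,0.206742
150,0.157591
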