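# name=iodine_solution_20mgml
# density_g_per_cm3=1.0144
energy_kev,mass_atten_cm2_per_g
10,8.39822
15,2.7244
20,1.29581
30,0.536984
33,0.46067
33.2,1.03288
35,0.920631
40,0.698736
50,0.465329
60,0.351269
80,0.249282
100,0.205623
150,0.161364
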