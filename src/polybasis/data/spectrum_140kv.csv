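energy_kev,relative_fluence
20,0.00258173
24,0.0091411
28,0.0159566
32,0.0225495
36,0.0287084
40,0.0343138
44,0.0392923
48,0.0435981
52,0.047204
56,0.0500964
60,0.0522719
64,0.0537357
68,0.0545005
72,0.0545849
76,0.0540138
80,0.052817
84,0.05103
88,0.0486931
92,0.0458522
96,0.0425584
100,0.0388687
104,0.0348467
108,0.0305633
112,0.0260976
116,0.0215393
120,0.0169911
124,0.0125729
128,0.0084299
132,0.00474735
136,0.00178852
140,5.53451e-05
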