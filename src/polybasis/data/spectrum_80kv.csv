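energy_kev,relative_fluence
20,0.00038058
22,0.00147199
24,0.00319876
26,0.00548538
28,0.00825638
30,0.0114363
32,0.0149495
34,0.0187207
36,0.0226744
38,0.0267349
40,0.030827
42,0.0348749
44,0.0388034
46,0.0425369
48,0.0459998
50,0.0491168
52,0.0518123
54,0.0540109
56,0.055637
58,0.0566152
60,0.0568699
62,0.0563258
64,0.0549073
66,0.0525389
68,0.0491451
70,0.0446505
72,0.0389795
74,0.0320568
76,0.0238067
78,0.0141538
80,0.00302262
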