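second,Hardness,Cohesiveness,MoistnessOfMass,AwarenessOfParticles
3,0.21,0.20,0.18,0.40
6,0.41,0.21,0.17,0.21
9,0.27,0.29,0.20,0.24
12,0.20,0.31,0.20,0.29
15,0.24,0.25,0.25,0.26
18,0.25,0.25,0.25,0.26
21,0.24,0.25,0.24,0.27
24,0.25,0.24,0.24,0.27
27,0.25,0.24,0.24,0.26
30,0.35,0.19,0.19,0.27
33,0.33,0.22,0.20,0.25
36,0.32,0.29,0.20,0.19
39,0.44,0.31,0.14,0.12
42,0.44,0.31,0.14,0.11
45,0.43,0.32,0.14,0.11
48,0.42,0.31,0.15,0.12
51,0.42,0.30,0.16,0.12
54,0.42,0.30,0.16,0.12
57,0.42,0.30,0.16,0.12
60,0.41,0.30,0.16,0.12
63,0.41,0.30,0.16,0.13
66,0.42,0.30,0.16,0.12
69,0.43,0.29,0.16,0.12
72,0.44,0.29,0.16,0.12
75,0.39,0.28,0.17,0.16
78,0.39,0.28,0.17,0.16
81,0.40,0.30,0.17,0.13
84,0.30,0.29,0.21,0.19
87,0.27,0.29,0.24,0.21
90,0.30,0.29,0.21,0.20
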