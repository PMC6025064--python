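second,Deformable,Springy,UniformBite,Dense,Toothpull
1,0.48,0.12,0.14,0.14,0.11
2,0.28,0.08,0.28,0.28,0.08
3,0.25,0.13,0.10,0.43,0.09
4,0.49,0.12,0.14,0.14,0.11
5,0.26,0.11,0.42,0.12,0.09
6,0.26,0.13,0.42,0.10,0.09
7,0.35,0.09,0.35,0.09,0.13
8,0.38,0.08,0.08,0.08,0.37
9,0.38,0.08,0.08,0.08,0.37
10,0.60,0.10,0.10,0.10,0.10
11,0.60,0.10,0.10,0.10,0.10
12,0.60,0.10,0.10,0.10,0.10
13,0.60,0.10,0.10,0.10,0.10
14,0.60,0.10,0.10,0.10,0.10
15,0.60,0.10,0.10,0.10,0.10
16,0.60,0.10,0.10,0.10,0.10
17,0.60,0.10,0.10,0.10,0.10
18,0.38,0.08,0.37,0.08,0.08
19,0.08,0.08,0.37,0.37,0.08
20,0.08,0.08,0.37,0.37,0.08
21,0.10,0.10,0.6,0.10,0.10
22,0.37,0.08,0.38,0.08,0.08
23,0.28,0.08,0.28,0.28,0.08
24,0.28,0.08,0.28,0.28,0.08
25,0.08,0.08,0.37,0.37,0.08
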