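second,FruitFlavor,Sweetness,Sourness
14,0.27,0.64,0.08
18,0.55,0.35,0.11
22,0.43,0.26,0.31
26,0.20,0.19,0.61
30,0.56,0.18,0.26
34,0.55,0.24,0.21
38,0.37,0.11,0.52
42,0.63,0.09,0.28
46,0.38,0.13,0.48
50,0.53,0.16,0.31
54,0.65,0.11,0.25
58,0.64,0.12,0.24
62,0.65,0.15,0.21
66,0.65,0.15,0.21
70,0.51,0.37,0.12
74,0.50,0.44,0.06
78,0.51,0.44,0.05
82,0.38,0.50,0.12
86,0.33,0.54,0.13
90,0.33,0.54,0.13
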