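second,HvC,HvM,HvA,CvM,CvA,MvA
3,0.04,-0.03,0.08,-0.02,0.10,0.16
6,-0.06,-0.15,-0.09,-0.04,0,0.04
9,0.13,-0.06,0,-0.1,-0.03,0.03
12,-0.07,0,0.06,-0.08,-0.01,0.06
15,0,0.01,0.02,0,0.01,-0.01
18,0,0,0,0,0.01,0
21,0.01,-0.01,0.02,0,0.01,0.03
24,0.01,-0.01,0.01,0,0.01,0.02
27,0,0.01,0,0,0.01,0.01
30,0.17,0.17,-0.33,0.04,0.04,0.04
33,0.12,0.15,-0.27,0.02,0,0.02
36,0.05,0.12,-0.06,-0.06,-0.08,-0.01
39,0.06,0.24,0.09,-0.01,-0.16,-0.02
42,0.06,0.25,0.08,0,-0.17,-0.03
45,0.05,0.24,0.07,-0.01,-0.18,-0.02
48,0.05,0.22,0.06,0.03,-0.17,-0.03
51,0.05,0.23,0.06,0.03,-0.17,-0.04
54,0.05,0.22,0.06,0.04,-0.16,-0.04
57,0.05,0.22,0.06,0.04,-0.17,-0.04
60,0.05,0.22,0.06,0.04,-0.17,-0.04
63,0.04,0.21,0.06,0.05,-0.17,-0.04
66,0.05,0.22,0.06,0.04,-0.17,-0.04
69,0.06,0.23,0.07,0.04,-0.16,-0.04
72,0.06,0.23,0.07,0.04,-0.16,-0.04
75,0.02,0.18,0.08,0.07,-0.12,-0.01
78,0.02,0.18,0.08,0.07,-0.13,-0.01
81,0.04,0.20,0.05,0.07,-0.16,-0.04
84,-0.02,0.06,0.08,0.05,-0.09,-0.02
87,-0.03,0.02,0.07,0.05,-0.07,-0.03
90,-0.02,0.07,0.07,0.07,-0.09,-0.01
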