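age,qx
0,0.00035
1,0.000355
2,0.00036
3,0.000365
4,0.000372
5,0.000378
6,0.000385
7,0.000393
8,0.000402
9,0.000411
10,0.000421
11,0.000432
12,0.000445
13,0.000458
14,0.000472
15,0.000488
16,0.000506
17,0.000525
18,0.000545
19,0.000568
20,0.000592
21,0.000619
22,0.000649
23,0.000681
24,0.000716
25,0.000754
26,0.000796
27,0.000841
28,0.000891
29,0.000945
30,0.001005
31,0.00107
32,0.001141
33,0.001218
34,0.001302
35,0.001394
36,0.001495
37,0.001605
38,0.001725
39,0.001856
40,0.001999
41,0.002156
42,0.002326
43,0.002513
44,0.002716
45,0.002939
46,0.003181
47,0.003446
48,0.003736
49,0.004052
50,0.004397
51,0.004774
52,0.005185
53,0.005635
54,0.006126
55,0.006661
56,0.007247
57,0.007886
58,0.008583
59,0.009345
60,0.010177
61,0.011086
62,0.012078
63,0.013162
64,0.014345
65,0.015637
66,0.017048
67,0.018588
68,0.02027
69,0.022107
70,0.024113
71,0.026304
72,0.028696
73,0.031308
74,0.034161
75,0.037275
76,0.040677
77,0.044391
78,0.048447
79,0.052875
80,0.057712
81,0.062993
82,0.06876
83,0.075058
84,0.081934
85,0.089444
86,0.097644
87,0.106598
88,0.116377
89,0.127054
90,0.138714
91,0.151447
92,0.16535
93,0.180533
94,0.197112
95,0.215217
96,0.234986
97,0.256575
98,0.280149
99,0.305892
100,0.334002
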