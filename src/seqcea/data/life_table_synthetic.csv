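age,annual_mortality
0,0.006
1,0.00043
2,0.000433
3,0.000436
4,0.00044
5,0.000444
6,0.000449
7,0.000454
8,0.000459
9,0.000465
10,0.000472
11,0.000479
12,0.000488
13,0.000497
14,0.000506
15,0.000517
16,0.00053
17,0.000543
18,0.000558
19,0.000574
20,0.000592
21,0.000611
22,0.000633
23,0.000657
24,0.000684
25,0.000713
26,0.000745
27,0.000781
28,0.00082
29,0.000863
30,0.000911
31,0.000963
32,0.001021
33,0.001085
34,0.001156
35,0.001234
36,0.00132
37,0.001414
38,0.001519
39,0.001634
40,0.001761
41,0.001901
42,0.002055
43,0.002226
44,0.002414
45,0.002621
46,0.00285
47,0.003102
48,0.00338
49,0.003687
50,0.004026
51,0.004399
52,0.004811
53,0.005265
54,0.005766
55,0.006318
56,0.006928
57,0.0076
58,0.008341
59,0.009159
60,0.010061
61,0.011056
62,0.012153
63,0.013363
64,0.014697
65,0.01617
66,0.017793
67,0.019584
68,0.021559
69,0.023738
70,0.026141
71,0.028791
72,0.031715
73,0.034939
74,0.038495
75,0.042417
76,0.046744
77,0.051515
78,0.056778
79,0.062583
80,0.068986
81,0.076047
82,0.083836
83,0.092427
84,0.101902
85,0.112353
86,0.12388
87,0.136594
88,0.150617
89,0.166084
90,0.183143
91,0.201959
92,0.222712
93,0.245602
94,0.270848
95,0.298695
96,0.329408
97,0.363283
98,0.400647
99,0.441857
100,0.487311
101,0.537445
102,0.59274
103,0.653729
104,0.7
105,0.7
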