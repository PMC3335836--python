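age,annual_q
15,0.004146
16,0.004160
17,0.004176
18,0.004194
19,0.004213
20,0.004234
21,0.004257
22,0.004283
23,0.004311
24,0.004342
25,0.004376
26,0.004414
27,0.004455
28,0.004500
29,0.004550
30,0.004605
31,0.004665
32,0.004732
33,0.004805
34,0.004885
35,0.004973
36,0.005070
37,0.005177
38,0.005294
39,0.005423
40,0.005565
41,0.005720
42,0.005892
43,0.006080
44,0.006288
45,0.006516
46,0.006767
47,0.007042
48,0.007345
49,0.007679
50,0.008045
51,0.008449
52,0.008892
53,0.009379
54,0.009916
55,0.010505
56,0.011153
57,0.011866
58,0.012650
59,0.013512
60,0.014460
61,0.015503
62,0.016649
63,0.017910
64,0.019296
65,0.020820
66,0.022497
67,0.024340
68,0.026367
69,0.028596
70,0.031047
71,0.033743
72,0.036707
73,0.039967
74,0.043551
75,0.047493
76,0.051827
77,0.056594
78,0.061835
79,0.067599
80,0.073937
81,0.080907
82,0.088571
83,0.096999
84,0.106268
85,0.116459
86,0.127667
87,0.139992
88,0.153544
89,0.168448
90,0.184836
91,0.202858
92,0.222676
93,0.244469
94,0.268434
95,0.294788
96,0.323767
97,0.355635
98,0.390678
99,0.429214
100,0.471590
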