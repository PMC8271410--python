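molecule_id,PS,MS,CS
1,50.733,55.710,62.419
2,57.837,54.414,70.497
3,54.702,53.951,74.645
4,53.765,58.411,76.761
5,51.594,54.430,59.291
6,54.788,58.776,79.569
9,56.667,58.159,80.267
10,48.301,48.648,34.540
11,56.974,58.361,81.129
12,59.214,59.652,88.565
13,57.526,62.455,90.223
14,46.754,53.730,43.984
15,60.261,48.748,65.275
16,55.174,53.059,62.587
18,51.739,61.670,81.201
19,50.613,53.869,55.063
20,61.828,56.043,83.315
21,59.743,47.605,60.642
22,56.985,61.494,88.196
23,46.574,51.513,36.415
24,50.741,48.690,43.771
25,57.937,61.921,90.695
26,55.000,66.484,88.768
27,48.062,54.728,50.537
29,55.790,53.374,64.633
31,55.890,52.077,62.105
33,57.809,54.456,70.747
34,54.998,62.107,86.001
35,59.593,57.332,83.023
36,52.978,56.362,70.563
37,63.410,58.137,89.614
38,55.095,58.726,79.796
39,58.382,64.565,93.673
40,53.988,54.565,65.097
41,59.806,48.917,64.348
42,50.645,53.764,55.049
43,58.173,63.262,92.168
44,60.472,60.682,93.996
45,50.950,48.487,43.310
48,59.166,61.223,90.877
49,50.075,59.706,72.572
50,49.330,55.678,56.752
51,49.461,52.917,48.494
52,60.068,41.767,58.896
53,48.198,57.865,61.615
54,44.215,38.509,14.237
55,59.243,63.288,93.809
56,52.388,52.759,56.244
57,46.600,56.159,53.336
58,52.568,66.686,86.330
59,60.472,60.682,93.996
60,62.142,60.081,93.801
61,60.028,55.127,78.122
62,47.218,45.482,26.500
63,53.948,60.093,81.574
64,55.251,57.275,75.959
65,50.753,49.440,46.755
66,62.080,60.168,94.067
67,55.945,63.837,89.974
68,49.737,55.682,59.719
69,43.235,51.439,29.886
70,53.591,57.129,72.018
71,48.967,55.600,55.668
72,34.005,61.398,62.223
73,48.682,37.079,25.795
74,47.394,53.408,44.307
75,42.093,56.075,46.193
76,57.124,51.931,63.293
78,57.964,58.741,85.128
79,52.080,58.986,75.962
80,55.455,59.350,82.678
81,63.311,60.652,94.955
82,40.683,55.810,43.790
83,53.855,54.972,66.221
84,47.792,46.413,29.600
86,47.246,54.512,47.469
87,44.090,63.495,67.402
88,31.567,56.544,47.519
89,50.567,45.006,36.692
90,51.033,57.709,70.135
91,58.794,52.697,67.806
92,51.110,57.428,69.475
93,38.732,50.418,25.175
94,49.677,56.691,63.460
95,51.612,39.231,38.738
96,50.716,44.696,37.174
97,51.033,57.709,70.135
98,49.576,51.478,45.294
99,48.567,58.439,64.597
101,54.120,49.688,54.593
102,49.677,56.691,63.460
103,48.879,59.590,68.261
104,51.399,43.820,39.281
105,22.051,66.738,75.164
106,37.133,55.909,44.280
107,40.979,58.222,52.755
108,50.356,52.020,48.741
109,57.796,60.055,86.599
110,50.426,48.015,39.848
111,60.748,54.667,78.467
112,42.758,50.425,27.825
113,41.305,50.123,25.711
114,45.632,52.818,39.093
115,44.264,50.525,31.501
116,60.087,47.239,61.154
117,57.489,54.592,70.919
118,46.867,55.849,52.467
119,41.126,51.845,29.131
120,23.833,32.945,0.240
121,37.530,39.004,6.780
122,50.160,57.683,66.126
123,49.449,57.237,62.548
124,49.217,52.803,46.521
125,35.000,45.774,13.029
126,59.742,54.379,73.484
128,44.885,49.017,29.168
131,37.731,52.188,30.241
132,48.683,54.837,52.710
133,52.406,57.826,73.068
136,55.272,43.873,48.766
138,37.551,55.567,42.118
139,34.033,56.214,46.441
140,49.381,51.854,44.752
141,54.419,48.726,52.452
142,49.549,47.546,36.330
143,44.001,39.951,15.026
144,30.790,59.308,57.608
145,44.858,45.424,21.100
146,47.708,48.258,31.664
147,51.697,54.749,62.187
148,43.867,43.268,16.047
149,26.750,40.848,4.596
150,49.542,50.205,42.800
151,42.035,39.152,10.233
152,47.398,40.260,23.944
154,28.227,58.385,55.058
155,45.577,49.031,30.561
158,33.236,55.042,40.348
160,49.039,47.847,34.447
161,43.484,53.569,37.484
162,43.448,53.694,37.567
163,52.614,55.499,66.179
164,43.981,43.946,17.431
166,44.549,48.599,26.236
167,36.432,59.307,56.086
168,45.575,48.689,28.220
170,44.321,49.409,29.298
171,44.514,53.524,39.336
172,28.530,54.541,37.749
173,39.364,48.431,18.817
174,46.630,43.739,22.688
175,29.743,47.470,13.265
176,52.210,47.876,45.561
177,52.552,55.468,65.328
179,48.790,44.680,29.598
180,43.234,51.712,30.582
181,43.164,56.096,47.201
182,47.599,50.822,38.525
184,47.169,50.452,36.552
185,34.935,46.142,13.124
186,46.193,42.368,21.388
187,28.077,46.347,11.322
188,42.491,45.731,16.529
189,43.676,53.130,36.085
190,45.756,52.131,37.782
191,42.498,53.366,34.827
192,49.392,39.556,29.639
193,40.695,44.963,13.686
195,48.284,48.900,35.669
196,51.013,49.047,46.589
197,31.670,47.313,13.816
198,30.236,41.261,5.979
200,45.785,40.797,20.186
201,45.450,38.554,17.126
202,47.098,34.293,21.403
203,31.091,48.457,16.630
207,45.193,49.078,30.333
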