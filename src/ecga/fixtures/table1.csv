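compound_id,pic50,pic50_calc,activity_class
1,8.699,8.255,high
2,7.602,7.871,low
3,8.155,7.769,high
4,8.699,8.784,high
5,7.602,7.886,low
6,6.108,5.638,low
7,6.450,6.125,low
8,5.000,5.342,low
9,7.137,6.108,low
10,5.000,6.704,low
11,5.890,3.370,low
12,5.206,5.370,low
13,5.339,4.533,low
14,7.959,7.643,high
15,7.328,7.825,low
16,7.114,7.258,low
17,5.900,6.050,low
18,5.862,5.163,low
19,5.431,6.451,low
20,5.522,6.439,low
21,5.289,5.481,low
22,7.721,6.644,high
23,8.301,7.494,high
24,5.000,5.355,low
25,5.759,5.940,low
26,5.000,4.957,low
27,9.301,9.301,high
28,9.097,8.755,high
29,7.824,7.630,high
30,8.398,7.526,high
31,8.699,7.277,high
32,6.541,7.866,low
33,6.541,6.917,low
34,7.796,7.635,high
35,5.000,4.572,low
36,7.357,7.323,low
37,7.051,6.647,low
38,7.357,7.368,low
39,8.398,8.331,high
40,8.523,8.252,high
41,8.523,8.962,high
42,8.222,8.654,high
43,7.854,8.311,high
44,7.699,9.410,high
45,8.000,7.422,high
46,7.114,7.299,low
47,8.046,6.612,high
48,8.699,8.915,high
49,8.523,8.462,high
50,8.699,8.342,high
51,9.000,7.799,high
52,8.523,8.293,high
53,7.770,8.583,high
54,8.699,9.277,high
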