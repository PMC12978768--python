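a_index,parameter_number,E
1,13,0.721
2,17,0.863
3,19,0.909
4,59,0.892
5,84,0.711
6,96,0.965
7,101,0.907
8,121,0.624
9,149,0.964
10,199,0.847
11,202,0.756
12,204,0.665
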