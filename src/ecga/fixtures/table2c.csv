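label,C1,C7,C9,N1,H9,N2
C1,0.090,0.003,0.002,0.008,0.009,0.007
C7,0.003,0.014,0.003,0.007,0.003,0.028
C9,0.002,0.003,0.013,0.009,0.004,0.003
N1,0.008,0.007,0.009,0.054,0.002,0.037
H9,0.009,0.003,0.004,0.002,0.010,0.006
N2,0.007,0.028,0.003,0.037,0.006,0.013
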