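label,C1,C7,C9,N1,H9,N2
C1,0.094,0.005,0.007,0.009,0.012,0.012
C7,0.005,0.017,0.003,0.004,0.003,0.029
C9,0.007,0.003,0.021,0.009,0.006,0.003
N1,0.009,0.004,0.009,0.054,0.006,0.038
H9,0.012,0.003,0.006,0.006,0.010,0.006
N2,0.012,0.029,0.003,0.038,0.006,0.018
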