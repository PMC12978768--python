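label,C1,C7,C9,N1,H9,N2
C1,0.094,0.003,0.005,0.006,0.008,0.009
C7,0.003,0.017,0.003,0.003,0.003,0.004
C9,0.005,0.003,0.008,0.006,0.005,0.003
N1,0.006,0.003,0.006,0.008,0.002,0.010
H9,0.008,0.003,0.005,0.002,0.001,0.003
N2,0.009,0.004,0.003,0.010,0.003,0.010
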