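label,C1,C7,C9,N1,H9,N2
C1,-0.136,2.582,3.743,4.622,5.445,3.410
C7,2.582,-0.063,2.400,2.160,3.094,1.506
C9,3.743,2.400,0.057,3.705,4.665,3.600
N1,4.622,2.160,3.705,0.313,0.955,1.224
H9,5.445,3.094,4.665,0.955,0.092,2.045
N2,3.410,1.506,3.600,1.224,2.045,-0.184
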