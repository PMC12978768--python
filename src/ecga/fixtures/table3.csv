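a_index,parameter_number,parameter_name,kappa
1,13,Mulliken charge of N2 atom,-17.633
2,17,Mulliken charge of C13 atom,10.552
3,19,Mulliken charge of O3 atom,0.354
4,59,Polarizability ZYY,-0.001
5,84,Perpendicular distance of the O3 atom to the C1-H9-C9 plane,1.130
6,96,Angle between the C1-H9-C9 plane and the O3-C11 line,0.172
7,101,Angle between the C1-H9-C9 surface and the O3-C10 line,-0.347
8,121,Angle between H9-N1-N2,1.274
9,149,Logarithm of the distance between O3 and N1,-0.327
10,199,Polar surface area (PSA),-0.004
11,202,Rel E(aq),0.001
12,204,Torsion angle of O3-O2-C5-C7,0.001
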