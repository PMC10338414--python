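channel,x,y,z
Fp1,-2.944,8.392,-0.699
Fp2,2.987,8.490,-0.708
AF3,-3.370,7.684,2.123
AF4,3.571,7.773,2.196
F7,-7.026,4.247,-1.142
F3,-5.024,5.311,4.219
Fz,0.031,5.851,6.646
F4,5.184,5.430,4.081
F8,7.304,4.442,-1.200
FC5,-7.721,1.864,2.446
FC1,-3.406,2.601,7.999
FC2,3.478,2.644,7.881
FC6,7.953,1.994,2.444
T7,-8.416,-1.602,-0.935
C3,-6.536,-1.163,6.436
Cz,0.040,-0.917,10.024
C4,6.712,-1.090,6.358
T8,8.508,-1.502,-0.949
CP5,-7.959,-4.655,3.095
CP1,-3.551,-4.729,9.131
CP2,3.838,-4.707,9.069
CP6,8.332,-4.610,3.121
P7,-7.243,-7.345,-0.249
P3,-5.301,-7.879,5.594
Pz,0.032,-8.111,8.261
P4,5.567,-7.856,5.656
P8,7.306,-7.307,-0.254
PO3,-3.651,-10.085,3.717
PO4,3.678,-10.085,3.640
O1,-2.941,-11.245,0.884
Oz,0.011,-11.489,1.466
O2,2.984,-11.216,0.880
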