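residue,value
A,0.0373
R,0.0959
N,0.0036
D,0.1263
C,0.0829
Q,0.0761
E,0.0058
G,0.0050
H,0.0242
I,0.0000
L,0.0000
K,0.0371
M,0.0823
F,0.0946
P,0.0198
S,0.0829
T,0.0941
W,0.0548
Y,0.0516
V,0.0057
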