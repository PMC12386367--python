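residue,halpha_ppm
A,4.32
C,4.55
D,4.64
E,4.35
F,4.62
G,3.96
H,4.73
I,4.17
K,4.32
L,4.34
M,4.48
N,4.74
P,4.42
Q,4.34
R,4.34
S,4.47
T,4.35
V,4.12
W,4.66
Y,4.55
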