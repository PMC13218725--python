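aa,pace_scholtz
A,0.00
C,0.68
D,0.69
E,0.40
F,0.54
G,1.00
H,0.61
I,0.41
K,0.26
L,0.21
M,0.24
N,0.65
P,3.16
Q,0.39
R,0.21
S,0.50
T,0.66
V,0.61
W,0.49
Y,0.53
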