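# Single-bond covalent radii in Å (Cordero et al. consensus values).
# Fe uses the low-spin value; adequate for first-shell contact perception.
H: 0.31
B: 0.84
C: 0.76
N: 0.71
O: 0.66
F: 0.57
NA: 1.66
MG: 1.41
P: 1.07
S: 1.05
CL: 1.02
K: 2.03
CA: 1.76
MN: 1.39
FE: 1.32
CO: 1.26
NI: 1.24
CU: 1.32
ZN: 1.22
BR: 1.20
I: 1.39
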