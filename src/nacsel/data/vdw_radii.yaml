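# Van der Waals radii in Å (Bondi set; Fe from common force-field practice).
H: 1.20
C: 1.70
N: 1.55
O: 1.52
F: 1.47
P: 1.80
S: 1.80
CL: 1.75
FE: 2.05
ZN: 1.39
MN: 2.05
CO: 2.00
NI: 1.63
CU: 1.40
BR: 1.85
I: 1.98
NA: 2.27
MG: 1.73
K: 2.75
CA: 2.31
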