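# Van der Waals radii (Angstrom) by element symbol, after Bondi (1964),
# J. Phys. Chem. 68:441, with common metals from Batsanov (2001).
# Loaded by xtalface.structure.load_radii; override with any file of the
# same two-column layout.
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
H	1.20
D	1.20
F	1.47
CL	1.75
BR	1.85
I	1.98
SE	1.90
B	1.92
SI	2.10
FE	2.00
ZN	1.39
MG	1.73
MN	2.00
CU	1.40
NI	1.63
CO	2.00
CA	2.31
NA	2.27
K	2.75
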