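# Interface residue propensities: ratio of the frequency of each amino acid
# at protein-protein interfaces to its frequency on the general protein
# surface. The residue-propensity feature sums log(propensity) over interface
# residues. This default table reflects the well-established enrichment of
# hydrophobic and aromatic residues (and Met, Cys) at interfaces and the
# depletion of charged Lys/Glu; regenerate from your own training set with
# xtalface.features.derive_propensity_table for dataset-matched values.
A	0.90
C	1.40
D	0.80
E	0.70
F	1.50
G	0.90
H	1.10
I	1.30
K	0.70
L	1.30
M	1.50
N	0.90
P	0.90
Q	0.90
R	1.00
S	0.80
T	0.90
V	1.20
W	1.60
Y	1.40
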