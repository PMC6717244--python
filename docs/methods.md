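# Methods

`xtalface` decides whether a protein–protein interface observed in a crystal
structure is part of the functional assembly or an artifact of lattice
packing.  The decision combines two kinds of evidence: the geometry and
composition of the interface itself, and the evolutionary covariation signal
between the alignment columns of residues that touch across the interface.
A biologically maintained contact constrains both partners, so its column
pair tends to co-vary; a packing contact does not.

## Surfaces and interfaces

Solvent accessible surface area (SASA) uses the Shrake–Rupley test-point
construction: each atom's solvent-expanded sphere (van der Waals radius +
probe radius, default probe 1.4 Å) carries `n_points` test points, and the
accessible fraction is the fraction of points outside every other expanded
sphere.  Default `n_points` is 3000.  Test points sit on a golden-spiral
(Fibonacci) lattice rather than a random cloud, so every SASA value is
reproducible bit-for-bit at fixed `n_points`; the discretization error of an
isolated two-sphere system is below 0.5 % at 3000 points and shrinks with
more points.  Van der Waals radii come from a packaged Bondi (1964) table;
the table is a plain TSV and can be replaced wholesale.  Atoms of elements
missing from the table either raise (strict mode, default) or fall back to a
configurable radius.

Buried surface area (BSA) of an atom or residue is SASA computed alone minus
SASA computed with the partner structure present as an occluder, clipped at
zero (the clipping absorbs point-discretization jitter of order 1e-2 Å²).

An interface exists when at least one non-hydrogen atom pair across the two
structures is closer than 5.5 Å with both atoms burying at least 0.1 Å².
The residue contact pairs of an interface are the residue-level projection
of those atom pairs, restricted to residues with complete main chains
(N, CA, C, O — residues with missing main-chain atoms are treated as
ambiguous and excluded) that are surface residues, i.e. whose relative SASA
exceeds 25 % of the residue type's reference maximum (Tien et al. 2013
theoretical values, packaged, replaceable).  Relative SASA is measured on
the **unbound** monomer: "surface residue" describes the subunit before
complexation, and it keeps the core criterion below self-consistent.  Core
residues are interface residues with BSA/SASA > 0.95 (strictly).

Crystal neighbors can be reconstructed from the unit cell and space group:
all space-group operators combined with lattice translations from the 3×3×3
neighborhood of the origin cell, keeping copies with any atom within a
cutoff (default 6.5 Å = contact distance + 1 Å margin).  Files without
crystal metadata (biological-assembly files) skip this step — the caller
supplies the partner structure directly.

## Alignments and the diversity criterion

Alignments live on the 21-state alphabet (20 amino acids + gap); columns are
the query's match states (A3M lowercase insertions removed; query-gap
columns dropped in other formats), and non-standard letters map to the gap
state.  Sequence weights follow the usual redundancy correction: a
sequence's weight is 1 / (number of alignment members at or above the
clustering identity threshold, itself included), pairwise identity being
matches over columns where both sequences are non-gapped.  The default
clustering threshold is 62 %.  The weight sum is the effective number of
non-redundant clusters; coupling estimation demands at least as many
clusters as alignment columns.  When the criterion fails at 62 % the
threshold escalates in 1 % steps up to 80 %; failure through 80 % is a
reportable outcome, not an error.

Polishing removes sequences whose identity to the query falls below a floor,
one at a time in ascending identity, stopping before the removal that would
break the diversity criterion.  This suppresses noise from distant homologs
whose oligomeric state may differ from the query's.  The schedule is greedy
one-at-a-time because a batch removal could overshoot the criterion
boundary; if even the first removal would break it, the alignment is
returned unchanged with a warning.

## Coupling scores

The built-in scorer is of the shrinkage inverse-covariance family.  Weighted
single and pair frequencies, mixed with a uniform pseudocount (default
weight 0.2; λ/21 on singles and λ/441 on pairs, which keeps pair marginals
consistent with singles), build the 21L×21L covariance matrix
`C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)`.  `C` is singular by construction
(block-constant null vectors from the sum-to-one constraints), so it is
shrunk toward its diagonal, `C ← (1−ρ)C + ρ diag(C)`, with ρ escalating
geometrically from 0.005 until a Cholesky factorization succeeds; the
inverse is the precision matrix.  This replaces the L1-penalized (graphical
lasso) estimator of the original PSICOV with a dense analogue that is
orders of magnitude faster and adequate at desk scale; external PSICOV or
CCMpred score files can be substituted whenever bit-faithful parity with
those tools is wanted.

Precision entries are normalized to partial correlations,
`θ_ij(a,b) / sqrt(θ_ii(a,a) θ_jj(b,b))`, before the norm.  Raw dense-inverse
entries have an alignment-dependent scale (on the synthetic fixtures,
planted couplings score ≈ 550 raw but ≈ 2.0 as partial correlations, with
noise below 0.04), and the covariation-count thresholds below assume the
O(1) scale on which PSICOV-family scores live.  `normalize="none"` restores
the raw entries.

Each 21×21 block reduces to one score per column pair via the L2,1 norm
(sum of row Euclidean norms; the symmetrized mean of the (i,j) and (j,i)
block norms, because L2,1 is not transpose-invariant) or the Frobenius norm,
both over the 20×20 non-gap sub-block.  The Average Product Correction then
removes background:

    corrected(i,j) = raw(i,j) − mean_i · mean_j / mean_all

with means over full rows/columns of the region (diagonal included, so any
exact product structure is annihilated identically).  For concatenated
hetero-oligomer alignments the correction runs block-wise — separately
within each intra-chain square and on each inter-chain rectangle — so the
weak inter-chain background is not estimated from the much stronger
intra-chain statistics.  A region whose mean is zero is passed through
uncorrected (nothing to remove).

## Features

Per interface, 65 geometric/compositional features plus one
covariation-count feature per threshold:

| feature | n | definition | default |
|---|---|---|---|
| AA | 20 | per-amino-acid BSA / total interface BSA | — |
| AAc | 20 | the same over core residues only | all-zero + flag if no cores |
| AApair | 21 | unordered group-pair frequencies over residue contact pairs; groups: small ACGPST, negative DE, positive HKR, aromatic FWY, hydrophobic ILMV, other NQ | all-zero + flag if no pairs |
| LD | 1 | mean number of other interface atoms (positive BSA, both sides) within a radius of each interface atom, self excluded | radius 12 Å |
| RP | 1 | Σ log propensity over interface residues | packaged interface/surface ratio table; regenerable from any interface set |
| GVI | 1 | gap volume / total BSA (Å) | grid 1.0 Å, gap reach 5.0 Å |
| Ncore | 1 | number of core residues | — |
| CS_t | 4 | number of residue contact pairs with coupling score > t | t ∈ {0.2, 0.4, 0.6, 0.8} |

The gap volume estimator counts grid voxels outside every atom whose
surface distance to the nearest atom of *each* side is at most the gap
reach; an externally computed gap volume (e.g. SurfNet) can be passed to
override the estimator, keeping only the normalization.  The first three
covariation-count thresholds are where score distributions of biological
and packing contacts segregate best in practice; the fourth extends the
ladder so a classifier can weigh the extreme tail, and all four are
configurable.

Two filters remove contact pairs whose apparent coupling could be inherited
from intra-chain structure rather than the interface: pairs whose mapped
columns are within 5 positions in sequence (same chain block only), and
pairs whose intra-chain copies — the residues of one chain at the two
mapped positions — have C-beta atoms within 8 Å.  Glycine gets a virtual
C-beta built from N/CA/C with ideal tetrahedral geometry.  For concatenated
hetero-oligomer alignments both filters apply only within a chain block:
cross-block column pairs have no intra-chain copy to inherit signal from.
Unscored pairs (sparse external score files) never count at any threshold.

## Classification

F-score ranking: `F = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s²⁺ + s²⁻)` with n−1 sample
variances.  When both class variances vanish the score is 0 if the class
means also agree (the feature is constant) and +∞ if they differ — a
feature constant within each class at different levels is a perfect
separator and must head the ranking, not trail it.  Selection evaluates
cross-validated SVM-RBF accuracy on top-k prefixes over a candidate ladder
(default 1, 2, 4, 8, 16, 32, 64) and keeps the smallest k attaining the best
mean accuracy.

Models: random forest (500 trees, seeded) and SVM with RBF kernel
(features standardized inside the pipeline with training-fold statistics; C
and γ tuned on a small logarithmic grid by internal CV, since the
originating protocol does not pin them).  Cross-validation is stratified;
feature selection and standardization are re-fit inside every training
fold, so no statistic of a test fold ever reaches a model — a property the
tests assert by corrupting test-fold labels and checking fold-model
fingerprints are unchanged.  Performance is summarized by sensitivity,
specificity, accuracy, the Matthews correlation coefficient (0 when any
marginal factor vanishes) and ROC AUC computed as the Mann–Whitney rank
statistic with midranks on ties.  The default decision threshold on the
random-forest score is 0.5 and configurable.

Training sets can be de-redundified at 30 % sequence identity by
single-linkage clustering with one representative per cluster.

## Synthetic test bed

The synthetic generators define the study conditions for every end-to-end
guarantee:

* **Toy complexes** are two straight strands (N, CA, C, O, CB per residue;
  3.8 Å CA spacing) facing each other across a controllable CB–CB gap
  (default 4.8 Å; anything ≥ 5.5 Å designs no contact).  The default
  antiparallel arrangement makes residue i face residue n−1−i, so most
  designed contacts are distant both in sequence and within a chain and
  survive the covariation-count filters.  Glycine is excluded from sampled
  sequences because the template realizes contacts through CB atoms.
* **Coupled alignments** sample columns independently from a per-column
  background (query state kept with probability 1 − mutation rate, default
  0.6) and overwrite planted pairs: with probability equal to the coupling
  strength (default 0.9) the second column is a fixed random bijection of
  the first, conditioned to map the query states onto each other.  This
  two-state co-assignment is a deliberate simplification of Potts/Gibbs
  sampling — transparent, fast, and strong enough to drive
  inverse-covariance recovery.
* **The default labeled dataset** is 20 biological + 20 crystallographic
  interfaces, 60-residue chains, 1500-sequence alignments, 8 planted pairs
  per biological interface at contact columns.  Those sizes keep the full
  pipeline (three SASA runs, sequence weighting, a 1260×1260 covariance
  inversion per interface) around two minutes on one CPU.

What the generators do **not** emulate: phylogenetic tree structure among
sequences (weights see star-shaped divergence only), gaps, real side-chain
packing, interface curvature, and any correlation between geometry and
label — the two classes share the same geometry distribution by design, so
the synthetic benchmark isolates the covariation channel.  Passing it shows
the machinery is correct, not that real crystal interfaces will separate
with the same margins; the headline numbers on curated PDB benchmarks
require real structures and deep alignments, which are outside desk scale.

## Numerical choices and degenerate inputs

* Altloc resolution: highest occupancy, alphabetical tie-break; hydrogens,
  waters, and non-amino-acid heteroatoms dropped on read; first model only.
* Pairwise identity with zero comparable columns is 0.
* Shrinkage escalation failing through ρ = 1 raises a degenerate-alignment
  error (happens only for pathological inputs such as single sequences with
  zero pseudocount).
* Coupling-rank ties break lexicographically by (i, j); unscored pairs get
  an explicit no-rank sentinel.
* A residue with BSA > 0 but zero unbound SASA (impossible up to jitter) is
  logged and treated as non-core.
* Degenerate feature sub-vectors (no cores, no contact pairs, no coupling
  matrix) are all-zero with flags rather than errors, so the vector arity
  is invariant.
* MCC is defined as 0 whenever a marginal factor is 0; AUC requires both
  classes.

## Known limitations

* The built-in scorer is not PSICOV: no L1 sparsity, so use the external
  score adapters for parity with published PSICOV/CCMpred numbers.
* The grid gap-volume estimator approximates surface distance by
  nearest-center distance minus that atom's radius; at 1 Å grid this is
  accurate to roughly the grid volume and is validated against a half-grid
  refinement, not against SurfNet.
* Sequential column mapping assumes the alignment query matches the chain
  sequence; partially resolved chains need an explicit column map.
* Ortholog pairing for hetero-oligomer alignments is consumed, not built:
  a pre-concatenated alignment with chain boundary indices is the input
  contract.
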