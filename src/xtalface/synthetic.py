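"""Desk-scale synthetic fixtures with known ground truth.

Two generators drive the test bed:

* :func:`make_toy_complex` builds a pair of straight poly-peptide strands
  (N, CA, C, O, CB per residue) facing each other across a controllable
  C-beta--C-beta gap.  In the default antiparallel arrangement residue ``i``
  of the query faces residue ``n - 1 - i`` of the partner, so most designed
  contact pairs are distant in sequence and in intra-chain space - they
  survive the covariation-count filters by construction.

* :func:`make_coupled_msa` samples alignments column-independently from a
  per-column background (query residue conserved at ``1 - mutation_rate``),
  then overwrites planted column pairs: with probability equal to the
  coupling strength the second column's state is a fixed random bijection of
  the first's.  This two-state co-assignment is a deliberate simplification
  of Potts sampling - analytically transparent and strong enough to drive
  inverse-covariance recovery.

* :func:`make_labeled_dataset` chains both through the full feature
  pipeline: biological interfaces get couplings planted at their true
  contact columns, crystallographic ones get coupling-free alignments of the
  same size and diversity.

Glycine is excluded from sampled sequences because the strand template
realizes contacts through C-beta atoms; an explicit sequence containing G
simply loses that residue's designed contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import LabeledDataset
from .covariation import compute_couplings
from .features import FeatureConfig, assemble_features, feature_names
from .interface import (
    assign_core,
    detect_interface,
    load_max_sasa,
    residue_contact_pairs,
)
from .msa import ALPHABET, Alignment, sequence_weights
from .structure import ONE_TO_THREE, Atom, Chain, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "CoupledMsaSpec",
    "DatasetSpec",
    "make_toy_complex",
    "make_coupled_msa",
    "make_labeled_dataset",
]

_AA19 = "ACDEFHIKLMNPQRSTVWY"   # no glycine: strand template needs CB
_CA_SPACING = 3.8               # A between consecutive CA along a strand
_CB_OFFSET = 1.53               # CA -> CB bond length toward the partner


@dataclass
class ToyComplexSpec:
    n_res: int = 60
    spacing: float = 4.8         # closest CB-CB approach between chains, A
    antiparallel: bool = True
    sequence: Optional[str] = None   # one-letter; sampled without G if None
    seed: int = 0
    with_cell: bool = False      # attach a generous P1 cell


@dataclass
class CoupledMsaSpec:
    length: int = 60
    n_seq: int = 1500
    query: Optional[str] = None
    planted_pairs: list = field(default_factory=list)  # [(i, j), ...] 0-based
    coupling_strength: float = 0.9
    mutation_rate: float = 0.6
    seed: int = 0


@dataclass
class DatasetSpec:
    n_bio: int = 20
    n_cry: int = 20
    n_res: int = 60
    n_seq: int = 1500
    n_planted: int = 8
    coupling_strength: float = 0.9
    mutation_rate: float = 0.6
    spacing_range: tuple = (4.5, 5.0)
    seed: int = 0
    config: Optional[FeatureConfig] = None


def _strand(sequence: str, chain_id: str, y: float, reverse: bool,
            cb_toward: float) -> Chain:
    """A straight strand along x; CB points in the ``cb_toward`` y-direction."""
    n = len(sequence)
    residues = []
    for idx, aa in enumerate(sequence):
        pos = n - 1 - idx if reverse else idx
        ca = np.array([pos * _CA_SPACING, y, 0.0])
        atoms = [
            Atom("N", "N", ca + np.array([-1.2, -0.6 * cb_toward, 0.0])),
            Atom("CA", "C", ca.copy()),
            Atom("C", "C", ca + np.array([1.2, -0.6 * cb_toward, 0.3])),
            Atom("O", "O", ca + np.array([1.2, -1.8 * cb_toward, 0.3])),
        ]
        if aa != "G":
            atoms.append(Atom("CB", "C",
                              ca + np.array([0.0, _CB_OFFSET * cb_toward,
                                             0.0])))
        residues.append(Residue(ONE_TO_THREE[aa], idx + 1, "", atoms))
    return Chain(chain_id, residues)


def make_toy_complex(spec: ToyComplexSpec) -> tuple:
    """Build (query, partner, true_contact_pairs).

    True pairs are 0-based residue index pairs ``(i on query, j on
    partner)`` designed to satisfy the interface definition; with spacing
    beyond the contact cutoff the list is empty.
    """
    if spec.n_res < 2:
        raise ValueError("need at least 2 residues per chain")
    if spec.spacing <= 2.0:
        raise ValueError("infeasible spacing: chains would clash")
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is None:
        seq = "".join(rng.choice(list(_AA19), size=spec.n_res))
    else:
        seq = spec.sequence.upper()
        if len(seq) != spec.n_res:
            raise ValueError("sequence length does not match n_res")

    # CA planes sit so that the facing CB-CB distance equals `spacing`
    ca_gap = spec.spacing + 2 * _CB_OFFSET
    query = Structure([_strand(seq, "A", 0.0, False, +1.0)])
    partner = Structure([_strand(seq, "B", ca_gap, spec.antiparallel, -1.0)])
    if spec.with_cell:
        extent = spec.n_res * _CA_SPACING + 40.0
        cell = (extent, ca_gap + 40.0, 40.0, 90.0, 90.0, 90.0)
        query.cell = partner.cell = cell
        query.space_group = partner.space_group = "P 1"

    true_pairs = []
    if spec.spacing < 5.5:
        for i in range(spec.n_res):
            j = spec.n_res - 1 - i if spec.antiparallel else i
            if seq[i] != "G" and seq[j] != "G":
                true_pairs.append((i, j))
    return query, partner, true_pairs


def make_coupled_msa(spec: CoupledMsaSpec) -> tuple:
    """Sample an alignment with planted pairwise couplings.

    Returns ``(Alignment, planted_pairs)``.  Row 0 is the query.  Each
    non-query row draws every column from the per-column background
    (query state kept with probability ``1 - mutation_rate``, otherwise a
    uniform other amino acid); each planted pair (i, j) then re-draws
    column j as a fixed random bijection of column i with probability
    ``coupling_strength``.  The bijection maps the query state of i to the
    query state of j, so the conserved states co-occur.
    """
    if spec.n_seq < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    if spec.query is None:
        query = rng.integers(0, 20, size=L)
    else:
        if len(spec.query) != L:
            raise ValueError("query length does not match spec.length")
        query = np.array([ALPHABET.index(c) if c in ALPHABET[:20] else 0
                          for c in spec.query.upper()])

    n = spec.n_seq
    keep = rng.random((n, L)) < (1.0 - spec.mutation_rate)
    # uniform over the 19 non-query states
    jitter = rng.integers(1, 20, size=(n, L))
    mutated = (query[None, :] + jitter) % 20
    mat = np.where(keep, query[None, :], mutated).astype(np.int8)
    mat[0] = query

    for (i, j) in spec.planted_pairs:
        if not (0 <= i < L and 0 <= j < L) or i == j:
            raise ValueError(f"bad planted pair {(i, j)}")
        perm = rng.permutation(20)
        # condition the bijection on the conserved states
        qi, qj = int(query[i]), int(query[j])
        k = int(np.where(perm == qj)[0][0])
        perm[k], perm[qi] = perm[qi], qj
        coupled = rng.random(n) < spec.coupling_strength
        coupled[0] = False
        mat[coupled, j] = perm[mat[coupled, i]]

    ids = ["query"] + [f"seq{k}" for k in range(1, n)]
    return Alignment(ids, mat), list(spec.planted_pairs)


def _eligible_planted_pairs(true_pairs: list, min_separation: int,
                            cb_min: float) -> list:
    """Contact pairs that survive the covariation-count filters, i.e. whose
    sequence separation exceeds ``min_separation`` and whose intra-chain
    C-beta separation (straight strand: separation * CA spacing) exceeds
    ``cb_min``."""
    out = []
    for i, j in true_pairs:
        sep = abs(i - j)
        if sep > min_separation and sep * _CA_SPACING > cb_min:
            out.append((min(i, j), max(i, j)))
    return sorted(set(out))


def make_labeled_dataset(spec: Optional[DatasetSpec] = None,
                         **kw) -> tuple:
    """End-to-end labeled dataset of synthetic interfaces.

    Biological rows pair a toy complex with an alignment carrying planted
    couplings at true contact columns; crystallographic rows use the same
    geometry with coupling-free alignments.  Returns ``(LabeledDataset,
    manifest DataFrame)``.
    """
    if spec is None:
        spec = DatasetSpec(**kw)
    config = spec.config or FeatureConfig()
    max_sasa = load_max_sasa()
    rng = np.random.default_rng(spec.seed)

    rows, labels, ids, kinds = [], [], [], []
    for idx in range(spec.n_bio + spec.n_cry):
        is_bio = idx < spec.n_bio
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        spacing = float(sub_rng.uniform(*spec.spacing_range))
        toy = ToyComplexSpec(n_res=spec.n_res, spacing=spacing,
                             seed=sub_seed)
        query, partner, true_pairs = make_toy_complex(toy)
        seq = query.chains[0].sequence()

        eligible = _eligible_planted_pairs(
            true_pairs, config.min_seq_separation, config.cb_distance_min)
        planted = []
        if is_bio:
            take = min(spec.n_planted, len(eligible))
            sel = sub_rng.choice(len(eligible), size=take, replace=False)
            planted = [eligible[k] for k in sorted(sel)]
        msa_spec = CoupledMsaSpec(
            length=spec.n_res, n_seq=spec.n_seq, query=seq,
            planted_pairs=planted,
            coupling_strength=spec.coupling_strength,
            mutation_rate=spec.mutation_rate, seed=sub_seed + 1)
        aln, _ = make_coupled_msa(msa_spec)
        sequence_weights(aln)

        iface = detect_interface(query, partner)
        if iface is None:
            raise RuntimeError("designed toy complex lost its interface")
        residue_contact_pairs(iface, max_sasa)
        assign_core(iface)
        # homodimer: both chains map onto the same alignment columns
        for rk in iface.residue_records:
            iface.msa_column_map[rk] = rk[2] - 1  # author number is 1-based

        cm = compute_couplings(aln)
        fv = assemble_features(iface, cm, config)
        rows.append(fv.values)
        labels.append(1 if is_bio else 0)
        kinds.append("biological" if is_bio else "crystallographic")
        ids.append(f"{'bio' if is_bio else 'cry'}{idx:03d}")

    X = pd.DataFrame(rows, columns=feature_names(config), index=ids)
    dataset = LabeledDataset(X, np.array(labels))
    manifest = pd.DataFrame({"id": ids, "label": kinds})
    return dataset, manifest
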