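"""High-level orchestration shared by the command-line interface and the
synthetic dataset generator: structure pair -> interface -> couplings ->
feature vector."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .covariation import CouplingMatrix, compute_couplings
from .features import FeatureConfig, FeatureVector, assemble_features
from .interface import (
    Interface,
    assign_core,
    detect_interface,
    load_max_sasa,
    residue_contact_pairs,
)
from .msa import Alignment, check_diversity, sequence_weights
from .structure import Structure

__all__ = ["assign_column_map", "extract_interface", "score_alignment",
           "interface_features"]


def assign_column_map(iface: Interface, aln: Alignment) -> None:
    """Map interface residues to alignment columns by sequential position.

    For a homomeric interface with a single-gene alignment both sides map
    onto the same columns; a concatenated hetero-oligomer alignment (with
    ``chain_boundaries``) assigns its blocks to the query chains first, then
    the partner chains.  Chain lengths must match the block widths - the
    alignment's query is required to be the structure's sequence.
    """
    L = aln.length
    if not aln.chain_boundaries:
        for s, side in ((iface.query, "Q"), (iface.partner, "P")):
            for ch in s.chains:
                if len(ch.residues) != L:
                    raise ValueError(
                        f"chain {ch.id} has {len(ch.residues)} residues but "
                        f"the alignment has {L} columns; supply an explicit "
                        "column map for partially resolved chains")
                for col, res in enumerate(ch.residues):
                    iface.msa_column_map[(side, ch.id, res.number,
                                          res.icode)] = col
        return
    edges = [0] + sorted(aln.chain_boundaries) + [L]
    blocks = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]
    chains = [("Q", ch) for ch in iface.query.chains] + \
             [("P", ch) for ch in iface.partner.chains]
    if len(blocks) != len(chains):
        raise ValueError(f"{len(chains)} chains but {len(blocks)} alignment "
                         "blocks")
    for (start, stop), (side, ch) in zip(blocks, chains):
        if stop - start != len(ch.residues):
            raise ValueError(
                f"chain {ch.id} has {len(ch.residues)} residues but its "
                f"alignment block has {stop - start} columns")
        for col, res in enumerate(ch.residues, start=start):
            iface.msa_column_map[(side, ch.id, res.number, res.icode)] = col


def extract_interface(query: Structure, partner: Structure,
                      config: Optional[FeatureConfig] = None,
                      n_points: int = 3000) -> Optional[Interface]:
    """Detect the interface and fill contact pairs and core assignment."""
    iface = detect_interface(query, partner, n_points=n_points,
                             radii=(config.radii if config else None))
    if iface is None:
        return None
    residue_contact_pairs(iface, load_max_sasa())
    assign_core(iface)
    return iface


def score_alignment(aln: Alignment, pseudocount: float = 0.2,
                    norm: str = "l21",
                    require_diversity: bool = True) -> CouplingMatrix:
    """Weight the alignment, check the diversity criterion and compute the
    APC-corrected coupling matrix."""
    report = check_diversity(aln)
    if require_diversity and not report.passes:
        raise ValueError(
            f"alignment fails the diversity criterion: {report.n_clusters:.1f}"
            f" clusters < {aln.length} columns even at "
            f"{report.threshold_used:.0f}% identity")
    sequence_weights(aln, report.threshold_used)
    return compute_couplings(aln, pseudocount, norm)


def interface_features(query: Structure, partner: Structure,
                       aln: Optional[Alignment] = None,
                       cm: Optional[CouplingMatrix] = None,
                       config: Optional[FeatureConfig] = None,
                       n_points: int = 3000,
                       require_diversity: bool = True
                       ) -> Optional[FeatureVector]:
    """Full feature pipeline for one structure pair; ``None`` when the two
    structures form no interface.  Either a pre-computed coupling matrix or
    an alignment (scored with the built-in method) supplies the CS part."""
    iface = extract_interface(query, partner, config, n_points)
    if iface is None:
        return None
    if cm is None and aln is not None:
        cm = score_alignment(aln, require_diversity=require_diversity)
    if aln is not None:
        assign_column_map(iface, aln)
    elif cm is not None and not iface.msa_column_map:
        # columns of an external score file follow the query sequence
        pseudo = Alignment(["q"], np.zeros((1, cm.length), dtype=np.int8))
        assign_column_map(iface, pseudo)
    return assemble_features(iface, cm, config)
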