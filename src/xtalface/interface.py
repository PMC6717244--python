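"""Interface detection, residue contact pairs and core/rim assignment.

An interface between a query and a partner structure exists when at least one
non-hydrogen atom pair lies closer than 5.5 Angstrom with both atoms burying
at least 0.1 A^2 of surface on complexation.  Residue contact pairs are the
residue-level projection of those atom pairs, restricted to surface residues
(relative SASA of the unbound monomer above 25% of the residue type's
theoretical maximum) with complete main chains.  Core residues are interface
residues that lose more than 95% of their accessible surface to the partner.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    Structure,
    compute_sasa,
    load_radii,
)

__all__ = [
    "Interface",
    "MaxSasaTable",
    "load_max_sasa",
    "detect_interface",
    "residue_contact_pairs",
    "assign_core",
    "dump_interface",
    "load_interface_records",
]

log = logging.getLogger(__name__)

DISTANCE_CUTOFF = 5.5     # A, strict upper bound for contact atom pairs
MIN_ATOM_BSA = 0.1        # A^2, inclusive lower bound for both atoms
REL_SASA_SURFACE = 0.25   # surface residue: rel SASA strictly above this
CORE_BURIAL = 0.95        # core residue: BSA/SASA strictly above this


class MaxSasaTable(dict):
    """Three-letter residue name -> reference maximal SASA (A^2)."""


def load_max_sasa(path=None) -> MaxSasaTable:
    if path is None:
        text = resources.files("xtalface.data").joinpath(
            "max_sasa.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = MaxSasaTable()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, v = line.split()
        table[name.upper()] = float(v)
    return table


# residue keys are (side, chain_id, number, icode) with side "Q" or "P"


@dataclass
class Interface:
    query: Structure
    partner: Structure
    query_chain_ids: list
    partner_chain_ids: list
    # (q_atom_key, p_atom_key, distance); atom key = (side, chain, num, icode, name)
    contact_atom_pairs: list
    # per-residue records keyed by (side, chain, num, icode):
    #   {"aa": three-letter, "sasa_alone", "sasa_complex", "bsa",
    #    "rel_sasa" (None until computed), "is_core" (None until assigned),
    #    "main_chain_complete": bool}
    residue_records: dict
    per_atom_bsa: dict          # atom key -> A^2 (interface-side atoms only)
    total_bsa: float
    is_homomeric: bool
    residue_contact_pairs: list = field(default_factory=list)
    msa_column_map: dict = field(default_factory=dict)  # residue key -> column

    def residue(self, key):
        """The Residue object behind a residue record key."""
        side, chain_id, num, icode = key
        s = self.query if side == "Q" else self.partner
        for ch in s.chains:
            if ch.id != chain_id:
                continue
            for res in ch.residues:
                if res.number == num and res.icode == icode:
                    return res
        return None

    @property
    def n_core(self) -> int:
        return sum(1 for r in self.residue_records.values()
                   if r.get("is_core"))


def _atom_arrays(s: Structure, side: str):
    keys, coords = [], []
    for ch, res, atom in s.iter_atoms():
        keys.append((side, ch.id, res.number, res.icode, atom.name))
        coords.append(atom.coord)
    return keys, np.asarray(coords, dtype=float).reshape(-1, 3)


def detect_interface(query: Structure, partner: Structure,
                     distance_cutoff: float = DISTANCE_CUTOFF,
                     min_atom_bsa: float = MIN_ATOM_BSA,
                     probe: float = 1.4, n_points: int = 3000,
                     radii: Optional[dict] = None) -> Optional[Interface]:
    """Detect the interface between two structures, or return ``None``.

    Runs four SASA computations (each side alone and in complex), finds all
    qualifying contact atom pairs and collects per-residue SASA/BSA records
    for every residue that buries surface or takes part in a contact.
    """
    if radii is None:
        radii = load_radii()
    q_alone = compute_sasa(query, probe, n_points, radii)
    p_alone = compute_sasa(partner, probe, n_points, radii)
    q_cplx = compute_sasa(query, probe, n_points, radii, context=partner)
    p_cplx = compute_sasa(partner, probe, n_points, radii, context=query)

    per_atom_bsa = {}
    for side, alone, cplx in (("Q", q_alone, q_cplx), ("P", p_alone, p_cplx)):
        for k, v in alone.per_atom_sasa.items():
            per_atom_bsa[(side,) + k] = max(0.0, v - cplx.per_atom_sasa[k])

    q_keys, q_xyz = _atom_arrays(query, "Q")
    p_keys, p_xyz = _atom_arrays(partner, "P")
    tree_p = cKDTree(p_xyz)
    pairs = []
    for qi, hits in enumerate(tree_p.query_ball_point(q_xyz, distance_cutoff)):
        for pj in hits:
            d = float(np.linalg.norm(q_xyz[qi] - p_xyz[pj]))
            if d >= distance_cutoff:
                continue
            qk, pk = q_keys[qi], p_keys[pj]
            if per_atom_bsa[qk] >= min_atom_bsa and \
                    per_atom_bsa[pk] >= min_atom_bsa:
                pairs.append((qk, pk, d))
    if not pairs:
        return None

    contact_residues = {k[0][:4] for k in pairs} | {k[1][:4] for k in pairs}

    records = {}
    for side, s, alone, cplx in (("Q", query, q_alone, q_cplx),
                                 ("P", partner, p_alone, p_cplx)):
        for ch, res in s.iter_residues():
            rk = (side, ch.id, res.number, res.icode)
            atom_bsas = [per_atom_bsa[(side, ch.id, res.number, res.icode,
                                       a.name)] for a in res.atoms]
            if max(atom_bsas) < min_atom_bsa and rk not in contact_residues:
                continue
            sk = (ch.id, res.number, res.icode)
            records[rk] = {
                "aa": res.name,
                "sasa_alone": alone.per_residue_sasa[sk],
                "sasa_complex": cplx.per_residue_sasa[sk],
                "bsa": max(0.0, alone.per_residue_sasa[sk]
                           - cplx.per_residue_sasa[sk]),
                "rel_sasa": None,
                "is_core": None,
                "main_chain_complete": res.has_complete_main_chain(),
            }

    total_bsa = sum(r["bsa"] for r in records.values())
    q_seqs = sorted(ch.sequence() for ch in query.chains)
    p_seqs = sorted(ch.sequence() for ch in partner.chains)
    return Interface(
        query=query, partner=partner,
        query_chain_ids=[c.id for c in query.chains],
        partner_chain_ids=[c.id for c in partner.chains],
        contact_atom_pairs=pairs,
        residue_records=records,
        per_atom_bsa={k: v for k, v in per_atom_bsa.items() if v > 0.0},
        total_bsa=total_bsa,
        is_homomeric=(q_seqs == p_seqs),
    )


def residue_contact_pairs(iface: Interface,
                          max_sasa: Optional[MaxSasaTable] = None,
                          rel_sasa_threshold: float = REL_SASA_SURFACE
                          ) -> list:
    """Residue contact pairs of an interface.

    A residue pair qualifies when some atom pair of the two residues is a
    contact atom pair and both residues (1) have all main-chain atoms
    (N, CA, C, O) and (2) are surface residues, i.e. relative SASA of the
    unbound monomer strictly above ``rel_sasa_threshold``.  The pair list is
    stored on the interface and returned.
    """
    if max_sasa is None:
        max_sasa = load_max_sasa()
    for rk, rec in iface.residue_records.items():
        ref = max_sasa.get(rec["aa"])
        if ref is None:
            raise KeyError(
                f"residue type {rec['aa']!r} missing from the maximal-SASA "
                "table")
        rec["rel_sasa"] = rec["sasa_alone"] / ref

    seen = set()
    pairs = []
    for qk, pk, _d in iface.contact_atom_pairs:
        rp = (qk[:4], pk[:4])
        if rp in seen:
            continue
        seen.add(rp)
        recs = [iface.residue_records[rp[0]], iface.residue_records[rp[1]]]
        if all(r["main_chain_complete"] for r in recs) and \
                all(r["rel_sasa"] > rel_sasa_threshold for r in recs):
            pairs.append(rp)
    pairs.sort()
    iface.residue_contact_pairs = pairs
    return pairs


def assign_core(iface: Interface, burial: float = CORE_BURIAL) -> Interface:
    """Mark core residues: interface residues with BSA/SASA > ``burial``."""
    for rk, rec in iface.residue_records.items():
        if rec["sasa_alone"] <= 0.0:
            if rec["bsa"] > 0.0:
                log.warning("residue %s has BSA>0 with zero SASA; "
                            "treated as non-core", rk)
            rec["is_core"] = False
        else:
            rec["is_core"] = bool(
                (rec["bsa"] / rec["sasa_alone"]) > burial)
    return iface


# ---------------------------------------------------------------------------
# JSON-lines serialization.  Format: the first line is a header object, then
# one object per interface residue (in sorted key order), then one object per
# contact atom pair and per residue contact pair, both referencing residues
# by their 0-based position in the residue line order.


def dump_interface(iface: Interface, path) -> None:
    res_keys = sorted(iface.residue_records)
    index = {k: i for i, k in enumerate(res_keys)}
    lines = [json.dumps({
        "type": "interface",
        "query_chains": iface.query_chain_ids,
        "partner_chains": iface.partner_chain_ids,
        "total_bsa": iface.total_bsa,
        "is_homomeric": iface.is_homomeric,
        "n_residues": len(res_keys),
    })]
    for k in res_keys:
        rec = iface.residue_records[k]
        lines.append(json.dumps({
            "type": "residue", "side": k[0], "chain": k[1],
            "number": k[2], "icode": k[3], **rec}))
    for qk, pk, d in iface.contact_atom_pairs:
        lines.append(json.dumps({
            "type": "contact_atom_pair",
            "i": index[qk[:4]], "j": index[pk[:4]],
            "atom_i": qk[4], "atom_j": pk[4], "distance": d}))
    for a, b in iface.residue_contact_pairs:
        lines.append(json.dumps({
            "type": "residue_contact_pair", "i": index[a], "j": index[b]}))
    Path(path).write_text("\n".join(lines) + "\n")


def load_interface_records(path) -> dict:
    """Load a dumped interface back into plain records (no structures).

    Returns ``{"header": ..., "residues": [...], "contact_atom_pairs": [...],
    "residue_contact_pairs": [...]}``.
    """
    out = {"header": None, "residues": [], "contact_atom_pairs": [],
           "residue_contact_pairs": []}
    for line in Path(path).read_text().splitlines():
        obj = json.loads(line)
        t = obj.pop("type")
        if t == "interface":
            out["header"] = obj
        elif t == "residue":
            out["residues"].append(obj)
        elif t == "contact_atom_pair":
            out["contact_atom_pairs"].append(obj)
        elif t == "residue_contact_pair":
            out["residue_contact_pairs"].append(obj)
    return out
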