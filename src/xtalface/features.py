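"""Interface feature vector: 65 geometric/compositional features plus the
covariation-signal (CS) counts.

Known features (65):

* ``AA``   - 20 values, per-amino-acid BSA fractions over interface residues
* ``AAc``  - 20 values, the same restricted to core residues
* ``AApair`` - 21 values, frequencies of unordered amino-acid group pairs
  over residue contact pairs (6 physicochemical groups)
* ``LD``   - local density: mean number of other interface atoms within a
  radius of each interface atom
* ``RP``   - residue propensity: sum of log interface propensities over
  interface residues
* ``GVI``  - gap volume index: grid-estimated volume of the empty space
  between the two sides, divided by total BSA (Angstrom)
* ``Ncore`` - number of core residues

CS features (one per threshold): the number of residue contact pairs whose
APC-corrected coupling score exceeds the threshold, after removing pairs
that could owe their signal to intra-chain structure - pairs closer than six
positions in sequence and pairs whose intra-chain C-beta copies are within
8 Angstrom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .covariation import CouplingMatrix
from .interface import Interface
from .structure import THREE_TO_ONE, Structure, load_radii

__all__ = [
    "AA_ORDER",
    "AA_GROUPS",
    "AaGroups",
    "FeatureConfig",
    "FeatureVector",
    "aa_composition",
    "aa_pair_frequency",
    "local_density",
    "residue_propensity",
    "gap_volume_index",
    "cs_score",
    "assemble_features",
    "load_propensity",
    "derive_propensity_table",
    "feature_names",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# six physicochemical groups partitioning the 20 amino acids
AA_GROUPS = {
    "small": tuple("ACGPST"),
    "negative": tuple("DE"),
    "positive": tuple("HKR"),
    "aromatic": tuple("FWY"),
    "hydrophobic": tuple("ILMV"),
    "other": tuple("NQ"),
}


class AaGroups(dict):
    """group name -> tuple of one-letter codes; must partition the 20."""

    @classmethod
    def default(cls) -> "AaGroups":
        return cls(AA_GROUPS)

    def validate(self) -> None:
        members = [aa for aas in self.values() for aa in aas]
        if sorted(members) != sorted(AA_ORDER):
            raise ValueError("amino-acid groups must partition the 20 "
                             "standard residues")

    def of(self, aa: str) -> str:
        for name, aas in self.items():
            if aa in aas:
                return name
        raise KeyError(aa)


def group_pair_labels(groups: AaGroups) -> list:
    names = list(groups)
    out = []
    for i, a in enumerate(names):
        for b in names[i:]:
            out.append(f"{a}|{b}")
    return out


DEFAULT_CS_THRESHOLDS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class FeatureConfig:
    cs_thresholds: tuple = DEFAULT_CS_THRESHOLDS
    ld_radius: float = 12.0
    gvi_grid: float = 1.0
    gvi_gap_max: float = 5.0
    min_seq_separation: int = 5     # exclude pairs with |col_i-col_j| <= this
    cb_distance_min: float = 8.0    # exclude pairs with intrachain CB-CB <= this
    propensity: Optional[dict] = None
    groups: Optional[AaGroups] = None
    radii: Optional[dict] = None


@dataclass
class FeatureVector:
    names: list
    values: np.ndarray
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def load_propensity(path=None) -> dict:
    """One-letter amino acid -> interface propensity (ratio scale)."""
    if path is None:
        text = resources.files("xtalface.data").joinpath(
            "propensity.tsv").read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, v = line.split()
        out[aa.upper()] = float(v)
    return out


def derive_propensity_table(interfaces: list, pseudo: float = 1.0) -> dict:
    """Recompute the propensity table from a set of detected interfaces:
    frequency of each amino acid among interface residues over its frequency
    among all surface residues of the same structures (add-``pseudo``
    smoothed)."""
    iface_counts = {aa: pseudo for aa in AA_ORDER}
    surf_counts = {aa: pseudo for aa in AA_ORDER}
    for iface in interfaces:
        for rec in iface.residue_records.values():
            aa = THREE_TO_ONE.get(rec["aa"])
            if aa:
                iface_counts[aa] += 1
        for s in (iface.query, iface.partner):
            for _, res in s.iter_residues():
                aa = res.one_letter
                if aa in surf_counts:
                    surf_counts[aa] += 1
    n_i = sum(iface_counts.values())
    n_s = sum(surf_counts.values())
    return {aa: (iface_counts[aa] / n_i) / (surf_counts[aa] / n_s)
            for aa in AA_ORDER}


# ---------------------------------------------------------------------------
# Individual features


def aa_composition(iface: Interface, core_only: bool = False) -> tuple:
    """Per-amino-acid BSA fractions; returns (20-vector, degenerate flag).

    Each amino acid's summed BSA over (core) interface residues divided by
    the corresponding total; all zeros with a flag when the total is zero
    (e.g. no core residues).
    """
    sums = dict.fromkeys(AA_ORDER, 0.0)
    for rec in iface.residue_records.values():
        if core_only and not rec.get("is_core"):
            continue
        aa = THREE_TO_ONE.get(rec["aa"])
        if aa is not None:
            sums[aa] += rec["bsa"]
    total = sum(sums.values())
    if total <= 0.0:
        return np.zeros(len(AA_ORDER)), True
    return np.array([sums[aa] / total for aa in AA_ORDER]), False


def aa_pair_frequency(pairs: list, iface: Interface,
                      groups: Optional[AaGroups] = None) -> tuple:
    """Frequencies of unordered group pairs over residue contact pairs.

    Returns (21-vector in :func:`group_pair_labels` order, degenerate flag).
    """
    if groups is None:
        groups = AaGroups.default()
    groups.validate()
    labels = group_pair_labels(groups)
    names = list(groups)
    counts = dict.fromkeys(labels, 0)
    for a, b in pairs:
        ga = groups.of(THREE_TO_ONE[iface.residue_records[a]["aa"]])
        gb = groups.of(THREE_TO_ONE[iface.residue_records[b]["aa"]])
        ia, ib = names.index(ga), names.index(gb)
        key = f"{names[min(ia, ib)]}|{names[max(ia, ib)]}"
        counts[key] += 1
    total = sum(counts.values())
    if total == 0:
        return np.zeros(len(labels)), True
    return np.array([counts[k] / total for k in labels]), False


def _interface_atom_coords(iface: Interface) -> np.ndarray:
    coords = []
    for key, bsa in iface.per_atom_bsa.items():
        if bsa <= 0.0:
            continue
        side, chain, num, icode, name = key
        res = iface.residue((side, chain, num, icode))
        atom = res.atom(name) if res is not None else None
        if atom is not None:
            coords.append(atom.coord)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def local_density(iface: Interface, radius: float = 12.0) -> float:
    """Mean count, over interface atoms of both sides, of other interface
    atoms within ``radius`` Angstrom (self excluded).  Interface atoms are
    atoms with positive BSA."""
    coords = _interface_atom_coords(iface)
    if len(coords) == 0:
        raise ValueError("interface has no atoms with positive BSA")
    tree = cKDTree(coords)
    neighbors = tree.query_ball_point(coords, radius)
    counts = np.array([len(n) - 1 for n in neighbors], dtype=float)
    return float(counts.mean())


def residue_propensity(iface: Interface,
                       table: Optional[dict] = None) -> float:
    """Sum of log interface propensities over interface residues."""
    if table is None:
        table = load_propensity()
    total = 0.0
    for rec in iface.residue_records.values():
        aa = THREE_TO_ONE.get(rec["aa"])
        if aa is None:
            continue
        if aa not in table:
            raise KeyError(f"propensity table missing amino acid {aa!r}")
        total += float(np.log(table[aa]))
    return total


def gap_volume_index(iface: Interface, grid: float = 1.0,
                     gap_max: float = 5.0,
                     radii: Optional[dict] = None,
                     external_gap_volume: Optional[float] = None) -> float:
    """Gap volume between the two sides divided by total BSA (Angstrom).

    Grid estimator: voxels outside every atom whose surface distance to the
    nearest atom of EACH side is at most ``gap_max`` count as gap volume.
    The scan is restricted to the box around the interface atoms.
    ``external_gap_volume`` (A^3, e.g. from SurfNet) overrides the
    estimator; only the normalization by total BSA is applied then.
    """
    if iface.total_bsa <= 0.0:
        raise ValueError("interface has zero BSA")
    if external_gap_volume is not None:
        return float(external_gap_volume) / iface.total_bsa
    if radii is None:
        radii = load_radii()

    def side_arrays(s: Structure):
        c, r = [], []
        for _, res, atom in s.iter_atoms():
            c.append(atom.coord)
            r.append(radii.get(atom.element.upper(), 1.8))
        return np.asarray(c), np.asarray(r)

    qc, qr = side_arrays(iface.query)
    pc, pr = side_arrays(iface.partner)
    icoords = _interface_atom_coords(iface)
    lo = icoords.min(axis=0) - gap_max
    hi = icoords.max(axis=0) + gap_max
    axes = [np.arange(lo[d], hi[d] + grid, grid) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    dq, iq = cKDTree(qc).query(pts, k=1)
    dp, ip = cKDTree(pc).query(pts, k=1)
    # surface distance approximated with the nearest-center atom's radius;
    # fine for a grid estimator at this resolution
    sq = dq - qr[iq]
    sp = dp - pr[ip]
    gap = (sq > 0) & (sp > 0) & (sq <= gap_max) & (sp <= gap_max)
    return float(gap.sum()) * grid ** 3 / iface.total_bsa


def cs_score(iface: Interface, cm: CouplingMatrix, thresholds=None,
             query: Optional[Structure] = None,
             min_seq_separation: int = 5,
             cb_distance_min: float = 8.0) -> dict:
    """Count residue contact pairs with coupling score above each threshold.

    Pairs are excluded when their signal could come from intra-chain
    structure rather than the interface: (a) mapped columns within the same
    chain block closer than ``min_seq_separation + 1`` positions in
    sequence, and (b) pairs whose intra-chain copies (the residues of the
    query-side chain at the two mapped positions) have C-beta atoms within
    ``cb_distance_min`` Angstrom.  Unscored (NaN) pairs never count.
    """
    if thresholds is None:
        thresholds = DEFAULT_CS_THRESHOLDS
    thresholds = sorted(thresholds)
    if not iface.residue_contact_pairs:
        return {t: 0 for t in thresholds}
    if not iface.msa_column_map:
        raise ValueError("interface has no residue -> MSA column map")

    bounds = sorted(b for b in cm.block_structure if 0 < b < cm.length)
    edges = [0] + bounds + [cm.length]

    def block_of(col: int) -> int:
        for b in range(len(edges) - 1):
            if edges[b] <= col < edges[b + 1]:
                return b
        raise ValueError(f"column {col} outside the coupling matrix")

    # intra-chain copies: map columns back to residues, preferring the query
    # side so the C-beta filter always measures a single chain's geometry
    col_res = {}
    for rk, col in iface.msa_column_map.items():
        if rk[0] == "Q" or col not in col_res:
            col_res[col] = rk

    counts = dict.fromkeys(thresholds, 0)
    n_skipped = 0
    n_mapped = 0
    for a, b in iface.residue_contact_pairs:
        ca = iface.msa_column_map.get(a)
        cb = iface.msa_column_map.get(b)
        if ca is None or cb is None:
            n_skipped += 1
            continue
        n_mapped += 1
        if ca == cb:
            continue  # same column: self-coupling carries no signal
        same_block = block_of(ca) == block_of(cb)
        if same_block:
            if abs(ca - cb) <= min_seq_separation:
                continue
            ra = iface.residue(col_res[ca]) if ca in col_res else None
            rb = iface.residue(col_res[cb]) if cb in col_res else None
            if ra is not None and rb is not None:
                cba, cbb = ra.cbeta(), rb.cbeta()
                if cba is not None and cbb is not None and \
                        float(np.linalg.norm(cba - cbb)) <= cb_distance_min:
                    continue
        v = cm.scores[ca, cb]
        if np.isnan(v):
            continue
        for t in thresholds:
            if v > t:
                counts[t] += 1
    if n_skipped:
        log.warning("%d contact pairs skipped: residues not mapped to MSA "
                    "columns", n_skipped)
    if n_mapped == 0:
        raise ValueError("no contact pair maps to MSA columns")
    return counts


# ---------------------------------------------------------------------------
# Assembly


def feature_names(config: Optional[FeatureConfig] = None) -> list:
    if config is None:
        config = FeatureConfig()
    groups = config.groups or AaGroups.default()
    names = [f"AA_{aa}" for aa in AA_ORDER]
    names += [f"AAc_{aa}" for aa in AA_ORDER]
    names += [f"AApair_{lab}" for lab in group_pair_labels(groups)]
    names += ["LD", "RP", "GVI", "Ncore"]
    names += [f"CS_{t:g}" for t in sorted(config.cs_thresholds)]
    return names


def assemble_features(iface: Interface, cm: Optional[CouplingMatrix] = None,
                      config: Optional[FeatureConfig] = None
                      ) -> FeatureVector:
    """The deterministic fixed-order feature vector (65 known + CS counts).

    Without a coupling matrix the CS features are zero and flagged.
    """
    if config is None:
        config = FeatureConfig()
    groups = config.groups or AaGroups.default()
    flags = {}

    aa, flags["AA_degenerate"] = aa_composition(iface, core_only=False)
    aac, flags["AAc_degenerate"] = aa_composition(iface, core_only=True)
    pair_freq, flags["AApair_degenerate"] = aa_pair_frequency(
        iface.residue_contact_pairs, iface, groups)
    ld = local_density(iface, config.ld_radius)
    rp = residue_propensity(iface, config.propensity)
    gvi = gap_volume_index(iface, config.gvi_grid, config.gvi_gap_max,
                           config.radii)
    ncore = float(iface.n_core)

    thresholds = sorted(config.cs_thresholds)
    if cm is None:
        cs = {t: 0.0 for t in thresholds}
        flags["CS_missing"] = True
    else:
        cs = cs_score(iface, cm, thresholds,
                      min_seq_separation=config.min_seq_separation,
                      cb_distance_min=config.cb_distance_min)
        flags["CS_missing"] = False

    values = np.concatenate([
        aa, aac, pair_freq,
        [ld, rp, gvi, ncore],
        [float(cs[t]) for t in thresholds],
    ])
    return FeatureVector(feature_names(config), values, flags)


def write_feature_table(rows: list, path, labels: Optional[list] = None,
                        ids: Optional[list] = None,
                        provenance: str = "") -> None:
    """Write feature vectors as a TSV with id/label/provenance columns."""
    if not rows:
        raise ValueError("no feature vectors to write")
    names = rows[0].names
    df = pd.DataFrame([fv.values for fv in rows], columns=names)
    df.insert(0, "id", ids if ids is not None else range(len(rows)))
    df.insert(1, "label", labels if labels is not None else "")
    df.insert(2, "provenance", provenance)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
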