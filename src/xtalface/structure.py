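"""Protein structure model, crystal symmetry expansion and surface areas.

The structure model is deliberately small: chains of residues of non-hydrogen
atoms with author numbering.  Files are parsed with :mod:`gemmi` and converted
into this model, dropping waters, hydrogens, heteroatoms and alternate
locations on the way in.

Solvent accessible surface area (SASA) follows Shrake & Rupley (1973): each
atom is covered with test points on its solvent-expanded sphere and the
accessible fraction is the fraction of points not buried inside any other
expanded sphere.  Test points are placed on a deterministic golden-spiral
(Fibonacci) lattice, so results are reproducible bit-for-bit for a fixed
``n_points``.  The buried surface area (BSA) of an atom or residue is the
SASA it loses when a partner structure is added as an occluder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "SasaResult",
    "BsaResult",
    "StructureError",
    "FormatError",
    "EmptyStructureError",
    "read_structure",
    "symmetry_mates",
    "compute_sasa",
    "compute_bsa",
    "load_radii",
    "fibonacci_sphere",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O", "OH2"}
_MAIN_CHAIN = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Base class for structure-related errors."""


class FormatError(StructureError):
    """The file could not be parsed under the requested format."""


class EmptyStructureError(StructureError):
    """No protein content remained after filtering."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(), self.occupancy)


@dataclass
class Residue:
    name: str               # three-letter code
    number: int             # author residue number
    icode: str = ""         # insertion code ("" if none)
    atoms: list = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple:
        return (self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_complete_main_chain(self) -> bool:
        return all(self.atom(n) is not None for n in _MAIN_CHAIN)

    def cbeta(self) -> Optional[np.ndarray]:
        """C-beta coordinate; for glycine a virtual C-beta is constructed
        from N/CA/C assuming ideal tetrahedral geometry."""
        cb = self.atom("CB")
        if cb is not None:
            return cb.coord
        n, ca, c = self.atom("N"), self.atom("CA"), self.atom("C")
        if n is None or ca is None or c is None:
            return None
        b = ca.coord - n.coord
        c_v = c.coord - ca.coord
        a = np.cross(b, c_v)
        return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_v + ca.coord

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """Chains of residues of non-hydrogen atoms, optionally with unit cell.

    ``cell`` is ``(a, b, c, alpha, beta, gamma)`` in Angstrom/degrees and
    ``space_group`` a Hermann-Mauguin symbol; both are ``None`` for files
    without crystal information (e.g. biological-assembly files).
    """

    chains: list = field(default_factory=list)
    cell: Optional[tuple] = None
    space_group: Optional[str] = None

    def iter_residues(self) -> Iterator[tuple]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch, res

    def iter_atoms(self) -> Iterator[tuple]:
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch, res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        out = [a.coord for _, _, a in self.iter_atoms()]
        return np.asarray(out, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.cell,
                         self.space_group)

    def transformed(self, rot: np.ndarray, tran: np.ndarray) -> "Structure":
        """Return a rigid-transformed copy (coords -> rot @ x + tran)."""
        s = self.copy()
        for _, _, atom in s.iter_atoms():
            atom.coord = rot @ atom.coord + tran
        return s


# ---------------------------------------------------------------------------
# Parsing


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by alphabetical altloc
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Waters, hydrogens and non-protein heteroatoms are removed; alternate
    locations are resolved to the highest-occupancy conformer (alphabetical
    altloc on ties); only the first model of multi-model files is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r} (pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    st.setup_entities()

    cell = None
    sg = None
    if st.cell and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
        sg = st.spacegroup_hm or None

    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]

    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if gres.name in _WATER_NAMES:
                continue
            if info is None or not info.is_amino_acid():
                continue
            by_name: dict = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(Atom(name, ga.element.name.upper(),
                                  np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                  ga.occ))
            if atoms:
                residues.append(Residue(gres.name, gres.seqid.num,
                                        gres.seqid.icode.strip(), atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise EmptyStructureError(f"no protein residues in {path}")
    return Structure(chains, cell, sg)


def write_pdb(s: Structure, path) -> None:
    """Write the structure as a minimal PDB file (CRYST1 if cell known)."""
    lines = []
    if s.cell is not None:
        a, b, c, al, be, ga = s.cell
        sg = (s.space_group or "P 1")[:11]
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
            f"{sg:<11s}{1:4d}"
        )
    serial = 1
    for ch in s.chains:
        for res in ch.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {ch.id[:1]}"
                    f"{res.number:4d}{res.icode[:1] or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Crystal symmetry


def symmetry_mates(s: Structure, contact_cutoff: float = 6.5) -> list:
    """All crystal symmetry/translation copies of ``s`` with at least one
    atom within ``contact_cutoff`` Angstrom of the input coordinates.

    The expansion applies every space-group operator combined with lattice
    translations from the 3x3x3 neighbourhood of the origin cell; the
    identity copy is excluded.  Requires cell parameters and a space group.
    """
    if s.cell is None or s.space_group is None:
        raise StructureError(
            "structure has no unit cell / space group; supply a pre-generated "
            "partner structure instead of requesting symmetry mates")
    sg = gemmi.find_spacegroup_by_name(s.space_group)
    if sg is None:
        raise StructureError(f"unknown space group {s.space_group!r}")
    cell = gemmi.UnitCell(*s.cell)
    orth = np.array(cell.orth.mat.tolist())
    frac_m = np.array(cell.frac.mat.tolist())

    xyz = s.coords()
    frac = xyz @ frac_m.T
    tree = cKDTree(xyz)
    den = float(gemmi.Op.DEN)

    mates = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / den
        tran = np.array(op.tran, dtype=float) / den
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    shift = tran + np.array([i, j, k], dtype=float)
                    is_identity = (
                        np.allclose(rot, np.eye(3))
                        and np.allclose(shift, 0.0)
                    )
                    if is_identity:
                        continue
                    new_frac = frac @ rot.T + shift
                    new_xyz = new_frac @ orth.T
                    d, _ = tree.query(new_xyz, k=1,
                                      distance_upper_bound=contact_cutoff)
                    if not np.any(np.isfinite(d)):
                        continue
                    # rebuild through the same rigid map in cartesian space
                    cart_rot = orth @ rot @ frac_m
                    cart_tran = orth @ shift
                    mates.append(s.transformed(cart_rot, cart_tran))
    return mates


# ---------------------------------------------------------------------------
# SASA


def load_radii(path=None) -> dict:
    """Load a van der Waals radii table (element -> Angstrom).

    With no argument the packaged Bondi table is used.
    """
    if path is None:
        text = resources.files("xtalface.data").joinpath(
            "vdw_radii.tsv").read_text()
    else:
        text = Path(path).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, r = line.split()
        out[el.upper()] = float(r)
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on a golden-spiral lattice."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * math.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom_sasa: dict       # (chain, resnum, icode, atom name) -> A^2
    per_residue_sasa: dict    # (chain, resnum, icode) -> A^2
    probe_radius: float
    n_points: int


@dataclass
class BsaResult:
    per_atom_bsa: dict
    per_residue_bsa: dict


def _flatten(s: Structure, radii: dict, strict: bool,
             fallback_radius: float):
    keys, coords, rads = [], [], []
    for ch, res, atom in s.iter_atoms():
        r = radii.get(atom.element.upper())
        if r is None:
            if strict:
                raise StructureError(
                    f"no van der Waals radius for element {atom.element!r}; "
                    "extend the radii table or pass strict=False")
            r = fallback_radius
        keys.append((ch.id, res.number, res.icode, atom.name))
        coords.append(atom.coord)
        rads.append(r)
    return keys, np.asarray(coords, dtype=float), np.asarray(rads)


def compute_sasa(s: Structure, probe: float = 1.4, n_points: int = 3000,
                 radii: Optional[dict] = None,
                 context: Optional[Structure] = None,
                 strict: bool = True,
                 fallback_radius: float = 1.8) -> SasaResult:
    """Shrake-Rupley SASA of every atom of ``s``.

    When ``context`` is given its atoms occlude but are not reported, which
    yields the "in complex" surface of ``s``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if radii is None:
        radii = load_radii()
    keys, coords, rads = _flatten(s, radii, strict, fallback_radius)
    if len(keys) == 0:
        raise EmptyStructureError("structure has no atoms")
    occ_coords, occ_rads = coords, rads
    if context is not None:
        _, ctx_coords, ctx_rads = _flatten(context, radii, strict,
                                           fallback_radius)
        occ_coords = np.vstack([coords, ctx_coords])
        occ_rads = np.concatenate([rads, ctx_rads])

    unit = fibonacci_sphere(n_points)
    ext = occ_rads + probe
    max_ext = float(ext.max())
    tree = cKDTree(occ_coords)

    per_atom = {}
    per_res: dict = {}
    n_target = len(keys)
    for idx in range(n_target):
        r_ext = rads[idx] + probe
        center = coords[idx]
        nbr = tree.query_ball_point(center, r_ext + max_ext)
        nbr = [j for j in nbr if j != idx]
        pts = center + r_ext * unit
        if nbr:
            nc = occ_coords[nbr]
            nr = ext[np.asarray(nbr)]
            # keep only real overlappers
            d = np.linalg.norm(nc - center, axis=1)
            close = d < (r_ext + nr)
            nc, nr = nc[close], nr[close]
            if len(nc):
                d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
        else:
            frac = 1.0
        area = 4.0 * math.pi * r_ext * r_ext * frac
        per_atom[keys[idx]] = area
        rk = keys[idx][:3]
        per_res[rk] = per_res.get(rk, 0.0) + area
    return SasaResult(per_atom, per_res, probe, n_points)


def compute_bsa(query: Structure, partner: Structure,
                probe: float = 1.4, n_points: int = 3000,
                radii: Optional[dict] = None,
                **kw) -> BsaResult:
    """Buried surface area of ``query`` caused by ``partner``.

    BSA = SASA(query alone) - SASA(query with partner as occluder),
    clipped at zero (test-point jitter can produce tiny negatives).
    """
    alone = compute_sasa(query, probe, n_points, radii, **kw)
    complexed = compute_sasa(query, probe, n_points, radii, context=partner,
                             **kw)
    per_atom = {k: max(0.0, alone.per_atom_sasa[k] - v)
                for k, v in complexed.per_atom_sasa.items()}
    per_res: dict = {}
    for k, v in per_atom.items():
        rk = k[:3]
        per_res[rk] = per_res.get(rk, 0.0) + v
    return BsaResult(per_atom, per_res)
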