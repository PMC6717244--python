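"""Structure parsing, symmetry expansion and surface-area computation."""

import math

import gemmi
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xtalface.structure import (
    Atom,
    Chain,
    EmptyStructureError,
    FormatError,
    Residue,
    Structure,
    compute_bsa,
    compute_sasa,
    fibonacci_sphere,
    load_radii,
    read_structure,
    symmetry_mates,
    write_pdb,
)

from conftest import make_residue, single_atom_structure


# ---------------------------------------------------------------------------
# SASA


@pytest.mark.parametrize("element,radius", [("C", 1.70), ("N", 1.55),
                                            ("O", 1.52), ("S", 1.80)])
def test_isolated_atom_sasa_is_full_expanded_sphere(element, radius):
    s = single_atom_structure(element)
    res = compute_sasa(s, probe=1.4, n_points=3000)
    expected = 4.0 * math.pi * (radius + 1.4) ** 2
    got = next(iter(res.per_atom_sasa.values()))
    assert got == pytest.approx(expected, rel=0.01)


@pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.5])
def test_two_equal_spheres_match_spherical_cap_formula(d):
    """For two overlapping equal spheres the buried cap area is analytic:
    each atom loses a cap of height h = R - d/2."""
    R = 1.70 + 1.4
    s = Structure([Chain("A", [Residue("ALA", 1, "", [
        Atom("CA", "C", np.zeros(3)),
        Atom("CB", "C", np.array([d, 0.0, 0.0]))])])])
    res = compute_sasa(s, n_points=3000)
    h = R - d / 2.0
    expected = 4.0 * math.pi * R * R - 2.0 * math.pi * R * h
    for v in res.per_atom_sasa.values():
        assert v == pytest.approx(expected, rel=0.02)


def test_sasa_error_shrinks_with_more_points():
    R = 3.1
    d = 2.0
    h = R - d / 2.0
    exact = 4.0 * math.pi * R * R - 2.0 * math.pi * R * h
    s = Structure([Chain("A", [Residue("ALA", 1, "", [
        Atom("CA", "C", np.zeros(3)),
        Atom("CB", "C", np.array([d, 0.0, 0.0]))])])])
    errs = []
    for n in (100, 1000, 10000):
        got = list(compute_sasa(s, n_points=n).per_atom_sasa.values())[0]
        errs.append(abs(got - exact))
    assert errs[2] < errs[0]


def test_fully_caged_atom_has_zero_sasa():
    cage_dirs = fibonacci_sphere(80)
    atoms = [Atom("X", "C", 2.5 * u) for u in cage_dirs]
    atoms.insert(0, Atom("CA", "C", np.zeros(3)))
    s = Structure([Chain("A", [Residue("ALA", 1, "", atoms)])])
    res = compute_sasa(s, n_points=3000)
    assert res.per_atom_sasa[("A", 1, "", "CA")] == 0.0


def test_per_residue_sasa_sums_atoms():
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0)),
                               make_residue("LEU", 2, (3.8, 0, 0))])])
    res = compute_sasa(s, n_points=600)
    for rk, total in res.per_residue_sasa.items():
        atoms = [v for k, v in res.per_atom_sasa.items() if k[:3] == rk]
        assert total == pytest.approx(sum(atoms), abs=1e-6)


def test_sasa_translation_exact_rotation_approximate():
    s = Structure([Chain("A", [make_residue("TRP", 1, (0, 0, 0)),
                               make_residue("PHE", 2, (3.8, 0, 0))])])
    base = compute_sasa(s, n_points=2000)
    shifted = s.transformed(np.eye(3), np.array([11.0, -3.0, 7.0]))
    res_t = compute_sasa(shifted, n_points=2000)
    for k, v in base.per_atom_sasa.items():
        assert res_t.per_atom_sasa[k] == pytest.approx(v, abs=1e-9)
    rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
    res_r = compute_sasa(s.transformed(rot, np.zeros(3)), n_points=2000)
    for k, v in base.per_atom_sasa.items():
        assert res_r.per_atom_sasa[k] == pytest.approx(v, rel=0.05, abs=0.5)


def test_sasa_against_biotite():
    """Independent numerical cross-check of the Shrake-Rupley implementation."""
    biotite_struc = pytest.importorskip("biotite.structure")
    radii = load_radii()
    s = Structure([Chain("A", [make_residue("ALA", i + 1, (3.8 * i, 0, 0))
                               for i in range(4)])])
    arr = biotite_struc.AtomArray(s.n_atoms())
    flat = [(ch, r, a) for ch, r, a in s.iter_atoms()]
    for i, (ch, r, a) in enumerate(flat):
        arr.coord[i] = a.coord
        arr.chain_id[i] = ch.id
        arr.res_id[i] = r.number
        arr.res_name[i] = r.name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    ref = biotite_struc.sasa(
        arr, probe_radius=1.4, point_number=2000,
        vdw_radii=np.array([radii[a.element] for _, _, a in flat]))
    mine = compute_sasa(s, n_points=2000)
    got = np.array([mine.per_atom_sasa[(c.id, r.number, r.icode, a.name)]
                    for c, r, a in flat])
    np.testing.assert_allclose(got, ref, rtol=0.03, atol=0.5)


def test_unknown_element_strict_vs_fallback():
    s = single_atom_structure("XX")
    with pytest.raises(Exception, match="radius"):
        compute_sasa(s, n_points=100)
    res = compute_sasa(s, n_points=100, strict=False, fallback_radius=2.0)
    expected = 4.0 * math.pi * (2.0 + 1.4) ** 2
    assert next(iter(res.per_atom_sasa.values())) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# BSA


def test_bsa_distant_partner_is_zero():
    q = single_atom_structure("C")
    p = single_atom_structure("C", (100.0, 0.0, 0.0))
    bsa = compute_bsa(q, p, n_points=500)
    assert all(v == 0.0 for v in bsa.per_atom_bsa.values())


def test_bsa_superposed_chains_bury_everything():
    q = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])])
    p = Structure([Chain("B", [make_residue("ALA", 1, (0, 0, 0))])])
    bsa = compute_bsa(q, p, n_points=1000)
    sasa = compute_sasa(q, n_points=1000)
    for k, v in bsa.per_atom_bsa.items():
        assert v > 0.0
        assert v <= sasa.per_atom_sasa[k] + 1e-6


def test_bsa_equals_independent_double_sasa_run():
    q = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])])
    p = Structure([Chain("B", [make_residue("LEU", 1, (0, 5.0, 0))])])
    bsa = compute_bsa(q, p, n_points=1000)
    alone = compute_sasa(q, n_points=1000)
    together = compute_sasa(q, n_points=1000, context=p)
    for k in bsa.per_residue_bsa:
        expected = alone.per_residue_sasa[k] - together.per_residue_sasa[k]
        assert bsa.per_residue_bsa[k] == pytest.approx(max(0.0, expected),
                                                       abs=1e-9)


# ---------------------------------------------------------------------------
# Parsing


PDB_FIXTURE = """\
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N
ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.40  0.00           N
ATOM      3  CA  ALA A   1       1.500   1.000   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.900   1.200   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       3.400   2.300   0.000  1.00  0.00           O
ATOM      6  H   ALA A   1       2.000   2.000   0.000  1.00  0.00           H
ATOM      7  N   GLY A   2       3.700   0.100   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   2       5.100   0.200   0.000  1.00  0.00           C
ATOM      9  C   GLY A   2       5.800   1.500   0.000  1.00  0.00           C
ATOM     10  O   GLY A   2       7.000   1.600   0.000  1.00  0.00           O
HETATM   11  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


def test_read_structure_filters_and_altloc(tmp_path):
    path = tmp_path / "f.pdb"
    path.write_text(PDB_FIXTURE)
    s = read_structure(path)
    assert len(s.chains) == 1
    chain = s.chains[0]
    assert len(chain.residues) == 2          # water removed
    names = {a.name for a in chain.residues[0].atoms}
    assert "H" not in names                   # hydrogens removed
    # altloc A (occupancy 0.6) wins over B
    np.testing.assert_allclose(chain.residues[0].atom("N").coord,
                               [0.0, 0.0, 0.0])


def test_read_structure_errors(tmp_path):
    with pytest.raises(FormatError):
        read_structure(tmp_path / "missing.pdb")
    only_water = tmp_path / "w.pdb"
    only_water.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  "
        "0.00           O\nEND\n")
    with pytest.raises(EmptyStructureError):
        read_structure(only_water)


def test_pdb_round_trip_preserves_model(tmp_path):
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0)),
                               make_residue("VAL", 2, (3.8, 0, 0))])],
                  cell=(30.0, 30.0, 30.0, 90.0, 90.0, 90.0),
                  space_group="P 1")
    path = tmp_path / "out.pdb"
    write_pdb(s, path)
    s2 = read_structure(path, format="pdb")
    assert [r.name for r in s2.chains[0].residues] == ["ALA", "VAL"]
    assert s2.cell == pytest.approx(s.cell)
    np.testing.assert_allclose(s2.coords(), s.coords(), atol=1e-3)


def test_mmcif_reader(tmp_path):
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])])
    pdb_path = tmp_path / "m.pdb"
    write_pdb(s, pdb_path)
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "m.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    s2 = read_structure(cif_path, format="mmcif")
    np.testing.assert_allclose(s2.coords(), s.coords(), atol=1e-3)


def test_virtual_cbeta_for_glycine():
    # ideal backbone geometry: N-CA 1.458 A, CA-C 1.525 A, N-CA-C 111.2 deg
    ang = math.radians(111.2)
    res = Residue("GLY", 1, "", [
        Atom("N", "N", np.array([1.458, 0.0, 0.0])),
        Atom("CA", "C", np.zeros(3)),
        Atom("C", "C", 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])),
        Atom("O", "O", np.array([2.0, 2.0, 0.0])),
    ])
    cb = res.cbeta()
    assert cb is not None
    assert np.linalg.norm(cb) == pytest.approx(1.53, abs=0.1)
    # virtual CB sits out of the N-CA-C plane
    assert abs(cb[2]) > 0.5


# ---------------------------------------------------------------------------
# Symmetry


def _p1_structure(extent=30.0):
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])],
                  cell=(extent, extent, extent, 90.0, 90.0, 90.0),
                  space_group="P 1")
    return s


def test_p1_translation_mate_found():
    # molecule at the origin of a 6 A cell: translated copies touch it
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])],
                  cell=(6.0, 50.0, 50.0, 90.0, 90.0, 90.0),
                  space_group="P 1")
    mates = symmetry_mates(s, contact_cutoff=5.0)
    # exactly the +x and -x translations are in range
    assert len(mates) == 2


def test_isolated_molecule_in_huge_cell_has_no_mates():
    s = _p1_structure(extent=200.0)
    assert symmetry_mates(s, contact_cutoff=6.5) == []


def test_missing_cell_raises_actionable_error():
    s = Structure([Chain("A", [make_residue("ALA", 1, (0, 0, 0))])])
    with pytest.raises(Exception, match="partner"):
        symmetry_mates(s)


def test_p21_mates_match_brute_force_operator_expansion():
    """Against an independent enumeration of all P2(1) operators over the
    3x3x3 translation block done directly with gemmi primitives."""
    cell = (10.0, 12.0, 14.0, 90.0, 90.0, 90.0)
    s = Structure([Chain("A", [make_residue("ALA", 1, (1.0, 2.0, 3.0)),
                               make_residue("SER", 2, (4.8, 2.0, 3.0))])],
                  cell=cell, space_group="P 1 21 1")
    cutoff = 9.0
    mates = symmetry_mates(s, contact_cutoff=cutoff)

    gcell = gemmi.UnitCell(*cell)
    orth = np.array(gcell.orth.mat.tolist())
    frac_m = np.array(gcell.frac.mat.tolist())
    xyz = s.coords()
    frac = xyz @ frac_m.T
    expected = []
    den = float(gemmi.Op.DEN)
    for op in gemmi.find_spacegroup_by_name("P 1 21 1").operations():
        rot = np.array(op.rot, float) / den
        tran = np.array(op.tran, float) / den
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    shift = tran + [i, j, k]
                    if np.allclose(rot, np.eye(3)) and \
                            np.allclose(shift, 0.0):
                        continue
                    new = (frac @ rot.T + shift) @ orth.T
                    dmin = np.sqrt(
                        ((new[:, None, :] - xyz[None, :, :]) ** 2
                         ).sum(-1)).min()
                    if dmin <= cutoff:
                        expected.append(np.sort(new.round(6), axis=0))
    got = sorted(np.sort(m.coords().round(6), axis=0).tobytes()
                 for m in mates)
    want = sorted(e.tobytes() for e in expected)
    assert got == want
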