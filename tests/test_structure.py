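import numpy as np
import pytest

from ringdock.data import BCHE_ACTIVE_SITE_127, BCHE_ACTIVE_SITE_35
from ringdock.fixtures import make_residue_scaffold, make_rigid_ring
from ringdock.structure import (Atom, Molecule, extract_active_site,
                                read_ligand, read_pdb, read_xyz, write_pdb,
                                write_xyz)

MINIMAL_PDB = (
    "ATOM      1  CA  GLY A   7       1.000   2.000   3.000  1.00  0.00"
    "           C\n"
    "END\n"
)

THREE_RES_PDB = "\n".join(
    f"ATOM  {i+1:>5d}  {an:<3s} {rn:>3s} A{num:>4d}    "
    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {an[0]:>2s}"
    for i, (an, rn, num, x, y, z) in enumerate([
        ("N", "SER", 1, 0.0, 0.0, 0.0),
        ("CA", "SER", 1, 1.5, 0.0, 0.0),
        ("N", "GLY", 2, 3.0, 1.0, 0.0),
        ("CA", "GLY", 2, 4.5, 1.0, 0.0),
        ("N", "ALA", 3, 6.0, 2.0, 0.0),
        ("CA", "ALA", 3, 7.5, 2.0, 0.0),
    ])
) + "\nEND\n"


class TestReadPdb:
    def test_minimal_record_identity_parse(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        mols = read_pdb(p)
        assert len(mols) == 1
        atom = mols[0].atoms[0]
        assert atom.element == "C"
        assert atom.residue_name == "GLY"
        assert atom.residue_number == 7
        np.testing.assert_allclose(atom.coords, [1.0, 2.0, 3.0])

    def test_three_residue_fixture_grouping(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(THREE_RES_PDB)
        mols = read_pdb(p)
        atoms = [a for m in mols for a in m.atoms]
        assert len(atoms) == 6
        assert {a.residue_number for a in atoms} == {1, 2, 3}

    def test_hetatm_flagged_non_protein(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1  C1  LIG A 900       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        mols = read_pdb(p)
        assert mols[0].atoms[0].het

    def test_unparseable_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            MINIMAL_PDB.replace("   1.000", "   x.000")
        )
        with pytest.raises(ValueError, match="line 1"):
            read_pdb(p)


class TestXyz:
    def test_equilateral_triangle_readback(self, tmp_path):
        s = 1.5
        h = s * np.sqrt(3) / 2
        p = tmp_path / "tri.xyz"
        p.write_text(
            f"3\ntriangle\nC 0.0 0.0 0.0\nC {s} 0.0 0.0\nC {s/2} {h} 0.0\n"
        )
        mol = read_ligand(p)
        assert mol.rigid
        c = mol.coords
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(c[i] - c[j]) == pytest.approx(1.5, abs=1e-9)

    def test_header_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("4\ncomment\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(ValueError, match="declares 4"):
            read_xyz(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_xyz(p)

    def test_roundtrip_precision(self, tmp_path, rng):
        mol = Molecule(
            atoms=[Atom(element=e, coords=rng.uniform(-9, 9, 3))
                   for e in ("C", "N", "O", "H", "S", "P")],
            name="random", rigid=True,
        )
        p = tmp_path / "rt.xyz"
        write_xyz(mol, p)
        back = read_xyz(p)
        assert back.elements == mol.elements
        np.testing.assert_allclose(back.coords, mol.coords, atol=1e-6)


class TestPdbRoundtrip:
    def test_roundtrip_at_pdb_precision(self, tmp_path, rng):
        coords = np.round(rng.uniform(-50, 50, (8, 3)), 3)
        mol = Molecule(
            atoms=[Atom(element="C", coords=c, residue_name="LIG",
                        residue_number=1, atom_name=f"C{i+1}", het=True)
                   for i, c in enumerate(coords)],
            name="lig",
        )
        p = tmp_path / "rt.pdb"
        write_pdb(mol, p)
        back = read_pdb(p)
        np.testing.assert_allclose(back[0].coords, coords, atol=1e-4)
        assert back[0].elements == mol.elements


class TestReadLigandFormats:
    def test_generated_cyclopropane_atom_count(self, tmp_path):
        ring = make_rigid_ring("cyclopropane")
        p = tmp_path / "cp.xyz"
        write_xyz(ring, p)
        mol = read_ligand(p)
        assert len(mol) == 9
        assert sorted(mol.elements) == ["C"] * 3 + ["H"] * 6

    def test_sdf_readback(self, tmp_path):
        # minimal V2000 block: 2 atoms, 1 bond
        sdf = (
            "probe\n  synthetic\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.5400    0.0000    0.0000 C   0  0\n"
            "  1  2  1  0\nM  END\n$$$$\n"
        )
        p = tmp_path / "eth.sdf"
        p.write_text(sdf)
        mol = read_ligand(p)
        assert mol.elements == ["C", "C"]
        assert np.linalg.norm(mol.coords[1] - mol.coords[0]) == pytest.approx(1.54)


class TestExtractActiveSite:
    def test_large_residue_selection(self):
        scaffold = make_residue_scaffold(BCHE_ACTIVE_SITE_127)
        model = extract_active_site(scaffold, BCHE_ACTIVE_SITE_127)
        assert model.n_residues == 127
        assert all(a.frozen for a in model.atoms if not a.is_hydrogen)

    def test_small_selection_on_large_scaffold(self):
        scaffold = make_residue_scaffold(BCHE_ACTIVE_SITE_127)
        model = extract_active_site(scaffold, BCHE_ACTIVE_SITE_35)
        assert model.n_residues == 35

    def test_exact_atoms_of_selection(self):
        scaffold = make_residue_scaffold([("SER", 1), ("GLY", 2), ("ALA", 3)])
        model = extract_active_site(scaffold, [("GLY", 2)])
        assert {a.residue_number for a in model.atoms} == {2}
        assert len(model.atoms) == 4  # N, CA, C, O backbone trace

    def test_order_independence(self):
        scaffold = make_residue_scaffold(BCHE_ACTIVE_SITE_35)
        fwd = extract_active_site(scaffold, BCHE_ACTIVE_SITE_35)
        rev = extract_active_site(scaffold, list(reversed(BCHE_ACTIVE_SITE_35)))
        key = lambda m: sorted(
            (a.residue_number, a.atom_name, tuple(np.round(a.coords, 6)))
            for a in m.atoms
        )
        assert key(fwd) == key(rev)

    def test_empty_selection(self):
        scaffold = make_residue_scaffold([("SER", 1)])
        with pytest.raises(ValueError, match="empty selection"):
            extract_active_site(scaffold, [])

    def test_missing_residue_named(self):
        scaffold = make_residue_scaffold([("SER", 1)])
        with pytest.raises(KeyError, match="HIS438"):
            extract_active_site(scaffold, [("HIS", 438)])

    def test_name_mismatch_guards_renumbering(self):
        scaffold = make_residue_scaffold([("SER", 1)])
        with pytest.raises(ValueError, match="not GLY"):
            extract_active_site(scaffold, [("GLY", 1)])


class TestAtomInvariants:
    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            Atom(element="Xx", coords=[0, 0, 0])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            Atom(element="C", coords=[0, np.nan, 0])

    def test_polar_hydrogen_implies_hydrogen(self):
        with pytest.raises(ValueError):
            Atom(element="C", coords=[0, 0, 0], is_polar_hydrogen=True)
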