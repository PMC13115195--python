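import numpy as np
import pytest

from ringdock.contacts import ContactSpec, contact_table, min_distance
from ringdock.fixtures import make_rigid_ring
from ringdock.sampling import Pose, apply_pose, random_rotation
from ringdock.structure import ActiveSiteModel, Atom, Molecule


def _receptor():
    atoms = [
        Atom(element="O", coords=[0, 0, 3.0], residue_name="SER",
             residue_number=198, atom_name="OG"),
        Atom(element="C", coords=[0.8, 0.4, 3.5], residue_name="SER",
             residue_number=198, atom_name="CB"),
        Atom(element="N", coords=[4.0, 0, 0], residue_name="HIS",
             residue_number=438, atom_name="NE2"),
        Atom(element="C", coords=[4.8, 0.5, 0.2], residue_name="HIS",
             residue_number=438, atom_name="CE1"),
        Atom(element="N", coords=[-3.0, 1.0, 0.5], residue_name="GLY",
             residue_number=116, atom_name="N"),
    ]
    return ActiveSiteModel(
        atoms=atoms,
        residue_index={198: [0, 1], 438: [2, 3], 116: [4]},
    )


def _ligand_at(coords_list, elements):
    return [Molecule(
        atoms=[Atom(element=e, coords=c)
               for e, c in zip(elements, coords_list)],
        rigid=True,
    )]


class TestMinDistance:
    def test_euclidean_readback(self):
        rec = _receptor()
        lig = _ligand_at([[0, 0, 0]], ["N"])
        row = min_distance(rec, lig, ContactSpec(residue=("SER", 198)))
        assert row.distance == pytest.approx(3.0)
        assert row.label == "N⋯O"
        assert row.residue == "Ser198"

    def test_matches_all_pairs_oracle(self, rng):
        rec = _receptor()
        ring = make_rigid_ring("aziridine")
        for _ in range(50):
            placed = apply_pose(ring, Pose(tuple(rng.uniform(-5, 5, 3)),
                                           random_rotation(rng)))
            spec = ContactSpec(residue=("HIS", 438))
            row = min_distance(rec, [placed], spec)
            lig_heavy = placed.coords[
                [i for i, e in enumerate(placed.elements) if e != "H"]]
            res_coords = np.array([rec.atoms[2].coords, rec.atoms[3].coords])
            oracle = np.min(np.linalg.norm(
                lig_heavy[:, None] - res_coords[None], axis=-1))
            assert row.distance == pytest.approx(oracle, abs=1e-9)

    def test_element_selector(self):
        rec = _receptor()
        lig = _ligand_at([[0, 0, 1.0], [2.0, 0, 0]], ["S", "C"])
        spec = ContactSpec(residue=("SER", 198), ligand_atom_selector="S")
        row = min_distance(rec, lig, spec)
        assert row.label == "S⋯O"
        assert row.distance == pytest.approx(2.0)

    def test_residue_atom_name_selector(self):
        rec = _receptor()
        lig = _ligand_at([[0, 0, 0]], ["N"])
        spec = ContactSpec(residue=("SER", 198), residue_atom_selector="CB")
        row = min_distance(rec, lig, spec)
        assert row.distance == pytest.approx(np.linalg.norm([0.8, 0.4, 3.5]))

    def test_nonexistent_residue(self):
        with pytest.raises(KeyError, match="TRP82"):
            min_distance(_receptor(), _ligand_at([[0, 0, 0]], ["C"]),
                         ContactSpec(residue=("TRP", 82)))

    def test_selector_matching_nothing_named(self):
        rec = _receptor()
        spec = ContactSpec(residue=("SER", 198), residue_atom_selector="ZZ9")
        with pytest.raises(ValueError, match="ZZ9"):
            min_distance(rec, _ligand_at([[0, 0, 0]], ["C"]), spec)

    def test_rigid_motion_invariance(self, rng):
        rec = _receptor()
        ring = make_rigid_ring("oxirane")
        placed = apply_pose(ring, Pose((1.0, 1.0, 1.0), (1, 0, 0, 0)))
        spec = ContactSpec(residue=("GLY", 116))
        d0 = min_distance(rec, [placed], spec).distance
        pose = Pose(tuple(rng.uniform(-10, 10, 3)), random_rotation(rng))
        world = Molecule(atoms=list(rec.atoms) + list(placed.atoms),
                         rigid=True)
        moved = apply_pose(world, pose)
        nrec = len(rec.atoms)
        rec2 = ActiveSiteModel(atoms=moved.atoms[:nrec],
                               residue_index=rec.residue_index)
        lig2 = Molecule(atoms=moved.atoms[nrec:], rigid=True)
        d1 = min_distance(rec2, [lig2], spec).distance
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestStrongFlag:
    def test_hetero_contact_flagged_at_cutoff(self):
        rec = _receptor()
        lig = _ligand_at([[-3.0, 1.0, 3.1]], ["N"])  # 2.6 Å from Gly116 N
        spec = ContactSpec(residue=("GLY", 116), strong_cutoff=3.0)
        assert min_distance(rec, lig, spec).strong

    def test_lower_cutoff_removes_flag(self):
        rec = _receptor()
        lig = _ligand_at([[-3.0, 1.0, 3.1]], ["N"])
        spec = ContactSpec(residue=("GLY", 116), strong_cutoff=2.0)
        assert not min_distance(rec, lig, spec).strong

    def test_carbon_contact_never_strong(self):
        rec = _receptor()
        lig = _ligand_at([[-3.0, 1.0, 2.0]], ["C"])  # 1.5 Å but C partner
        spec = ContactSpec(residue=("GLY", 116), strong_cutoff=3.2)
        assert not min_distance(rec, lig, spec).strong

    def test_flag_monotone_in_cutoff(self, rng):
        rec = _receptor()
        ring = make_rigid_ring("aziridine")
        placed = [apply_pose(ring, Pose(tuple(rng.uniform(-4, 4, 3)),
                                        random_rotation(rng)))
                  for _ in range(40)]
        flags_per_cutoff = []
        for cutoff in (2.0, 3.0, 4.0, 6.0):
            flags = set()
            for i, p in enumerate(placed):
                for num in (198, 438, 116):
                    name = {198: "SER", 438: "HIS", 116: "GLY"}[num]
                    spec = ContactSpec(residue=(name, num),
                                       strong_cutoff=cutoff)
                    if min_distance(rec, [p], spec).strong:
                        flags.add((i, num))
            flags_per_cutoff.append(flags)
        for small, large in zip(flags_per_cutoff, flags_per_cutoff[1:]):
            assert small <= large


class TestContactTable:
    def test_rows_in_spec_order(self):
        rec = _receptor()
        lig = _ligand_at([[0, 0, 0]], ["N"])
        specs = [ContactSpec(residue=("HIS", 438)),
                 ContactSpec(residue=("SER", 198)),
                 ContactSpec(residue=("GLY", 116))]
        df = contact_table(rec, lig, specs)
        assert list(df["residue"]) == ["His438", "Ser198", "Gly116"]
        assert len(df) == 3

    def test_empty_specs_error(self):
        with pytest.raises(ValueError):
            contact_table(_receptor(), _ligand_at([[0, 0, 0]], ["C"]), [])
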