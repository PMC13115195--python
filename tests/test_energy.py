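import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringdock.energy import (COULOMB_KJ_A, SurrogateParams, binding_energy,
                             score_surrogate, score_surrogate_batch)
from ringdock.fixtures import make_rigid_ring
from ringdock.sampling import Pose, apply_pose, random_rotation
from ringdock.structure import ActiveSiteModel, Atom, Molecule


def _one_atom_receptor(element="C", charge=None):
    atom = Atom(element=element, coords=np.zeros(3), residue_name="REC",
                residue_number=1, frozen=True, charge=charge)
    return ActiveSiteModel(atoms=[atom], residue_index={1: [0]})


class TestSurrogate:
    def test_lj_minimum_closed_form(self):
        """Two neutral atoms at r = σ·2^(1/6) score exactly −ε."""
        params = SurrogateParams()
        sigma = params.sigma["C"]
        eps = params.epsilon["C"]
        rec = _one_atom_receptor("C")
        lig = Molecule(
            atoms=[Atom(element="C",
                        coords=[sigma * 2 ** (1 / 6), 0, 0])], rigid=True)
        res = score_surrogate(rec, [lig], params)
        assert res.energy == pytest.approx(-eps, abs=1e-9)
        assert res.backend_id == "surrogate"

    def test_no_ligands_zero(self):
        assert score_surrogate(_one_atom_receptor(), []).energy == 0.0

    def test_hand_summed_three_atom_toy(self):
        """Receptor C at origin + diatomic H ligand: energy equals the
        manually summed pair terms."""
        params = SurrogateParams(charges={"C": 0.2, "H": -0.1})
        rec = _one_atom_receptor("C")
        lig = Molecule(atoms=[Atom(element="H", coords=[3.0, 0, 0]),
                              Atom(element="H", coords=[3.0, 1.0, 0])],
                       rigid=True)

        def pair(el_a, el_b, r, qa, qb):
            sig = 0.5 * (params.sigma[el_a] + params.sigma[el_b])
            eps = np.sqrt(params.epsilon[el_a] * params.epsilon[el_b])
            return (4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                    + COULOMB_KJ_A * qa * qb / r)

        expected = pair("C", "H", 3.0, 0.2, -0.1) \
            + pair("C", "H", np.sqrt(10.0), 0.2, -0.1)
        res = score_surrogate(rec, [lig], params)
        assert res.energy == pytest.approx(expected, abs=1e-9)
        # intra-ligand H..H pair (1 Å apart, hugely repulsive in LJ terms)
        # must not contribute
        assert abs(res.energy) < 50.0

    def test_beyond_cutoff_exactly_zero(self):
        params = SurrogateParams(cutoff=12.0)
        rec = _one_atom_receptor("C")
        lig = Molecule(atoms=[Atom(element="C", coords=[12.5, 0, 0])],
                       rigid=True)
        assert score_surrogate(rec, [lig], params).energy == 0.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_global_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rec = _one_atom_receptor("O", charge=-0.3)
        lig = make_rigid_ring("aziridine")
        lig = apply_pose(lig, Pose((3.5, 0.5, -0.2), (1, 0, 0, 0)))
        e0 = score_surrogate(rec, [lig]).energy

        pose = Pose(tuple(rng.uniform(-20, 20, 3)), random_rotation(rng))
        # move receptor and ligand together with the same rigid motion
        both = Molecule(atoms=list(rec.atoms) + list(lig.atoms), rigid=True)
        moved = apply_pose(both, pose)
        rec2 = ActiveSiteModel(atoms=moved.atoms[:1], residue_index={1: [0]})
        lig2 = Molecule(atoms=moved.atoms[1:], rigid=True)
        e1 = score_surrogate(rec2, [lig2]).energy
        assert e1 == pytest.approx(e0, abs=1e-6)

    def test_missing_element_parameters(self):
        params = SurrogateParams(epsilon={"C": 0.3}, sigma={"C": 3.4})
        rec = _one_atom_receptor("C")
        lig = Molecule(atoms=[Atom(element="N", coords=[3, 0, 0])], rigid=True)
        with pytest.raises(KeyError, match="N"):
            score_surrogate(rec, [lig], params)

    def test_batch_matches_single(self, cage, probe, rng):
        params = SurrogateParams()
        rec_arrays = (cage.coords, *params.atom_arrays(cage))
        lig_par = params.atom_arrays(probe)
        positions = rng.uniform(-5, 5, (50, 1, 3))
        batch = score_surrogate_batch(rec_arrays, [positions], [lig_par],
                                      params)
        for i, pos in enumerate(positions):
            placed = probe.with_coords(pos)
            assert batch[i] == pytest.approx(
                score_surrogate(cage, [placed], params).energy, abs=1e-9)

    def test_ligand_ligand_term_included(self):
        params = SurrogateParams()
        rec = _one_atom_receptor("C")
        a = Molecule(atoms=[Atom(element="C", coords=[100.0, 0, 0])], rigid=True)
        b = Molecule(
            atoms=[Atom(element="C",
                        coords=[100.0 + params.sigma["C"] * 2 ** (1 / 6), 0, 0])],
            rigid=True)
        res = score_surrogate(rec, [a, b], params)
        assert res.energy == pytest.approx(-params.epsilon["C"], abs=1e-9)


class TestBindingEnergy:
    def test_additive_null(self):
        assert binding_energy(-100.0, -60.0, -40.0, 1) == pytest.approx(0.0)

    def test_two_ligand_arithmetic(self):
        assert binding_energy(-250.0, -60.0, -40.0, 2) == pytest.approx(-110.0)

    def test_surrogate_consistency(self, cage, probe):
        placed = probe.with_coords(np.array([[1.5, -1.0, 0.8]]))
        e_complex = score_surrogate(cage, [placed]).energy
        e_site = score_surrogate(cage, []).energy
        e_lig = 0.0  # single atom: no intra pairs, no inter-molecular sum
        assert binding_energy(e_complex, e_site, e_lig, 1) == \
            pytest.approx(e_complex)

    @given(st.floats(-500, 500), st.floats(-500, 500), st.floats(-500, 500))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, ec, es, el):
        b = binding_energy(ec, es, el, 2)
        assert b == pytest.approx(ec - es - 2 * el, rel=1e-12, abs=1e-9)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            binding_energy(0, 0, 0, 0)
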