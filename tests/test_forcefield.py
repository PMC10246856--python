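"""Energies, forces and their consistency (finite-difference oracles)."""

import numpy as np
import pytest

from chromix.dynamics import build_neighbor_list
from chromix.forcefield import (
    WCA_CUTOFF,
    ForceField,
    SingularGeometryError,
    bending_energy_forces,
    confinement_energy_forces,
    indenter_force,
    pair_lj_energy_forces,
    spring_energy_forces,
    total_energy,
)
from chromix.model_core import EU, PolymerSystem


def numerical_gradient(energy_fn, positions, h=1e-6):
    """Central-difference gradient of a scalar energy over positions."""
    grad = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            p = positions.copy()
            p[i, d] += h
            ep = energy_fn(p)
            p[i, d] -= 2 * h
            em = energy_fn(p)
            grad[i, d] = (ep - em) / (2 * h)
    return grad


def assert_forces_match_gradient(energy_fn, force_fn, positions, tol=1e-6):
    forces = force_fn(positions)
    grad = numerical_gradient(energy_fn, positions)
    scale = max(1.0, np.abs(forces).max())
    assert np.allclose(forces, -grad, atol=tol * scale)


class TestSprings:
    def test_rest_length_zero_energy(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e, f = spring_energy_forces(pos, [[0, 1]], 100.0)
        assert e == pytest.approx(0.0)
        assert np.allclose(f, 0.0)

    def test_hand_value_at_1p1_sigma(self):
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        e, _ = spring_energy_forces(pos, [[0, 1]], 100.0)
        assert e == pytest.approx(0.5, rel=1e-9)  # 0.5*100*0.1^2

    def test_forces_are_negative_gradient(self, rng):
        pos = rng.normal(scale=2.0, size=(8, 3))
        bonds = [[i, i + 1] for i in range(7)]
        assert_forces_match_gradient(
            lambda p: spring_energy_forces(p, bonds, 100.0)[0],
            lambda p: spring_energy_forces(p, bonds, 100.0)[1],
            pos,
        )

    def test_coincident_beads_error(self):
        pos = np.zeros((2, 3))
        with pytest.raises(SingularGeometryError):
            spring_energy_forces(pos, [[0, 1]], 100.0)


class TestBending:
    def test_collinear_is_zero(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        e, f = bending_energy_forces(pos, [[0, 1, 2]], 5.0)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_right_angle_hand_value(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])
        e, _ = bending_energy_forces(pos, [[0, 1, 2]], 5.0)
        assert e == pytest.approx(5.0, rel=1e-12)  # k*(1 - cos 90)

    def test_forces_are_negative_gradient(self, rng):
        pos = rng.normal(scale=1.5, size=(6, 3))
        triples = [[i, i + 1, i + 2] for i in range(4)]
        assert_forces_match_gradient(
            lambda p: bending_energy_forces(p, triples, 5.0)[0],
            lambda p: bending_energy_forces(p, triples, 5.0)[1],
            pos,
        )

    def test_degenerate_bond_error(self):
        pos = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(SingularGeometryError):
            bending_energy_forces(pos, [[0, 1, 2]], 5.0)


def _lj_setup(positions, eps=1.0, cutoff=2.5):
    n = len(positions)
    ff = ForceField.homopolymer(eps, cutoff=cutoff)
    types = np.full(n, EU)
    chain = np.arange(n, dtype=np.int32)  # disconnected: all pairs count

    def parts(p):
        nl = build_neighbor_list(p, cutoff, 0.0, chain_id=chain)
        return pair_lj_energy_forces(p, types, ff.eps_matrix,
                                     ff.cutoff_matrix, nl, chain_id=chain)

    return parts


class TestLennardJones:
    def test_minimum_depth(self):
        parts = _lj_setup(np.array([[0.0, 0, 0], [2 ** (1 / 6), 0, 0]]))
        e, _ = parts(np.array([[0.0, 0, 0], [2 ** (1 / 6), 0, 0]]))
        assert e == pytest.approx(-1.0, rel=1e-12)

    def test_zero_crossing_at_sigma(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e, _ = _lj_setup(pos)(pos)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_value_at_cutoff_boundary(self):
        # evaluated just inside the 2.5 sigma truncation
        r = 2.5 - 1e-9
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        e, _ = _lj_setup(pos)(pos)
        assert e == pytest.approx(4 * (2.5 ** -12 - 2.5 ** -6), rel=1e-6)
        assert e == pytest.approx(-0.0163, abs=1e-4)

    def test_forces_are_negative_gradient(self, rng):
        pos = rng.uniform(-2, 2, size=(12, 3))
        # push apart overlapping beads so the force cap stays inactive
        from scipy.spatial.distance import pdist
        while pdist(pos).min() < 0.8:
            pos *= 1.1
        parts = _lj_setup(pos)
        assert_forces_match_gradient(lambda p: parts(p)[0],
                                     lambda p: parts(p)[1], pos)

    def test_eu_het_pair_is_never_attractive(self):
        # excluded-volume cutoff: energy >= 0 at every separation
        ff = ForceField.block_copolymer()
        types = np.array([0, 1])  # EU, HET
        chain = np.array([0, 1], np.int32)
        for r in np.linspace(0.85, 3.0, 40):
            pos = np.array([[0.0, 0, 0], [r, 0, 0]])
            nl = build_neighbor_list(pos, 2.5, 0.0, chain_id=chain)
            e, _ = pair_lj_energy_forces(pos, types, ff.eps_matrix,
                                         ff.cutoff_matrix, nl, chain_id=chain)
            assert e >= -1e-12

    def test_shifted_variant_vanishes_at_cutoff(self):
        pos = np.array([[0.0, 0, 0], [2.5 - 1e-9, 0, 0]])
        ff = ForceField.homopolymer(1.0, lj_shifted=True)
        types = np.zeros(2, int)
        chain = np.array([0, 1], np.int32)
        nl = build_neighbor_list(pos, 2.5, 0.0, chain_id=chain)
        e, _ = pair_lj_energy_forces(pos, types, ff.eps_matrix,
                                     ff.cutoff_matrix, nl, chain_id=chain,
                                     lj_shifted=True)
        assert e == pytest.approx(0.0, abs=1e-6)


class TestConfinementWall:
    def test_zero_inside(self):
        e, f = confinement_energy_forces(np.zeros((1, 3)), 10.0, 200.0)
        assert e == 0.0 and np.allclose(f, 0.0)

    def test_hand_value_beyond_edge(self):
        pos = np.array([[10.0 - 0.5 + 0.1, 0, 0]])
        e, f = confinement_energy_forces(pos, 10.0, 200.0)
        assert e == pytest.approx(1.0, rel=1e-9)  # 0.5*200*0.1^2
        assert f[0, 0] < 0  # inward

    def test_forces_are_negative_gradient(self, rng):
        pos = rng.normal(scale=6.0, size=(10, 3))
        assert_forces_match_gradient(
            lambda p: confinement_energy_forces(p, 5.0, 200.0)[0],
            lambda p: confinement_energy_forces(p, 5.0, 200.0)[1],
            pos,
        )


class TestIndenter:
    def test_zero_inside(self):
        f = indenter_force(np.array([[1.0, 0, 0]]), 10.0, 5.0)
        assert np.allclose(f, 0.0)

    def test_magnitude_one_sigma_out(self):
        f = indenter_force(np.array([[6.0, 0, 0]]), 10.0, 5.0)
        assert np.linalg.norm(f[0]) == pytest.approx(10.0, rel=1e-9)

    def test_force_points_inward(self, rng):
        pos = rng.normal(size=(20, 3)) * 8.0
        f = indenter_force(pos, 10.0, 5.0)
        radial = np.einsum("ij,ij->i", f, pos)
        assert np.all(radial <= 1e-12)


class TestTotalEnergy:
    def _system(self, rng, n=30):
        pos = rng.normal(scale=3.0, size=(n, 3))
        return PolymerSystem(
            positions=pos,
            chain_id=np.repeat([0, 1], n // 2).astype(np.int32),
            confinement_radius=8.0,
        )

    def test_relaxed_phantom_chain_is_zero(self):
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5)
        sys_ = PolymerSystem(positions=pos, chain_id=np.zeros(5, np.int32))
        ff = ForceField()  # eps = 0 everywhere
        terms = total_energy(sys_, ff, build_neighbor_list(pos, 2.5, 0.0))
        assert terms["total"] == pytest.approx(0.0, abs=1e-12)

    def test_additivity_of_terms(self, rng):
        sys_ = self._system(rng)
        ff = ForceField.homopolymer(0.5)
        nl = build_neighbor_list(sys_.positions, 2.5, 0.0,
                                 chain_id=sys_.chain_id)
        terms = total_energy(sys_, ff, nl)
        assert terms["total"] == pytest.approx(
            terms["spring"] + terms["bend"] + terms["lj"] + terms["wall"],
            abs=1e-12,
        )

    def test_rotation_invariance_of_intra_terms(self, rng):
        from scipy.spatial.transform import Rotation
        sys_ = self._system(rng)
        sys_.confinement_radius = np.inf
        ff = ForceField.homopolymer(0.5)

        def tot(p):
            s2 = sys_.copy()
            s2.positions = p
            nl = build_neighbor_list(p, 2.5, 0.0, chain_id=sys_.chain_id)
            return total_energy(s2, ff, nl)["total"]

        e0 = tot(sys_.positions)
        rot = Rotation.random(random_state=3).as_matrix()
        e1 = tot(sys_.positions @ rot.T)
        assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-9)


class TestForceFieldContainer:
    def test_asymmetric_matrix_rejected(self):
        eps = np.zeros((4, 4))
        eps[0, 1] = 0.3
        with pytest.raises(ValueError):
            ForceField(eps_matrix=eps)

    def test_small_cutoff_rejected(self):
        ff = ForceField()
        with pytest.raises(ValueError):
            ff.set_pair("EU", "EU", 1.0, 1.0)

    def test_bending_constant_encodes_persistence_length(self):
        assert ForceField(k_bend=5.0).k_bend == 5.0  # l_p = 5 beads
        assert ForceField.homopolymer(0.3, k_bend=1.0).k_bend == 1.0

    def test_yaml_roundtrip(self, tmp_path):
        ff = ForceField.block_copolymer(0.25, 0.5, lamin_lad_eps=1.0)
        path = tmp_path / "ff.yaml"
        ff.to_yaml(path)
        back = ForceField.from_yaml(path)
        assert np.allclose(back.eps_matrix, ff.eps_matrix)
        assert np.allclose(back.cutoff_matrix, ff.cutoff_matrix)
        assert back.k_spring == ff.k_spring
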