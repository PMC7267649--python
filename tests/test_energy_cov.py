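import math

import numpy as np
import pytest

from conftest import fd_gradient
from genff.constants import BOHR_PER_ANGSTROM
from genff.energy_cov import (
    assemble_bond_params,
    assemble_covalent_terms,
    bend_energy,
    bond_energy,
    bonded_repulsion,
    covalent_energy,
    threebody_correction,
    torsion_energy,
)
from genff.io import Molecule
from genff.topology import perceive_topology


def diatomic_terms(table, z=1, r_angstrom=0.74):
    mol = Molecule([z, z], [[0, 0, 0], [r_angstrom, 0, 0]])
    topo = perceive_topology(mol, table)
    return mol, topo, assemble_covalent_terms(mol, topo, table)


class TestBondStretch:
    def test_minimum_depth_and_zero_gradient(self, table):
        mol, topo, terms = diatomic_terms(table)
        b = terms.bonds
        xyz = np.array([[0, 0, 0], [b.r0[0], 0, 0]])
        e, g = bond_energy(xyz, b)
        assert e == pytest.approx(-b.k_b[0], abs=1e-14)
        assert np.abs(g).max() < 1e-12

    def test_dissociated_tail(self, table):
        mol, topo, terms = diatomic_terms(table)
        b = terms.bonds
        xyz = np.array([[0, 0, 0], [b.r0[0] + 10.0, 0, 0]])
        e, _ = bond_energy(xyz, b)
        assert abs(e) < b.k_b[0] * 1e-20

    def test_curvature_matches_2_k_alpha(self, table):
        """Second derivative at r0 equals 2 k_b alpha_b (harmonic limit)."""
        mol, topo, terms = diatomic_terms(table)
        b = terms.bonds
        h = 1e-4
        r0 = b.r0[0]

        def e_of_r(r):
            return bond_energy(np.array([[0, 0, 0], [r, 0, 0]]), b)[0]

        second = (e_of_r(r0 + h) - 2 * e_of_r(r0) + e_of_r(r0 - h)) / h**2
        assert second == pytest.approx(2 * b.k_b[0] * b.alpha_b[0], rel=1e-6)

    def test_pi_bond_deeper_well_shorter_r0(self, molecules, table):
        """For pi bonds k_b grows and r0 shrinks with bond order."""
        topo_e = perceive_topology(molecules["ethylene"], table)
        bp = assemble_bond_params(molecules["ethylene"], topo_e, table)
        cc = [t for t in range(len(bp)) if bp.k_b[t] == bp.k_b.max()][0]
        single_k = table.pair_k_bond(6, 6)
        single_r0 = table.r0_bond(6, 6, 1.0) * BOHR_PER_ANGSTROM
        assert bp.k_b[cc] > single_k
        assert bp.r0[cc] < single_r0


class TestBend:
    def test_zero_at_reference_angle(self, table):
        # sp-hybridized linear reference evaluated at 180 deg: no energy,
        # no gradient, no singularity
        mol = Molecule([6, 8, 8], [[0, 0, 0], [1.16, 0, 0], [-1.16, 0, 0]])
        topo = perceive_topology(mol, table)
        assert topo.hybridization[0] == "sp"
        terms = assemble_covalent_terms(mol, topo, table)
        e, g = bend_energy(mol.coords_bohr, terms)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.isfinite(g)) and np.abs(g).max() < 1e-12

    def test_arm_dissociation_damps_to_zero(self, molecules, table):
        mol = molecules["water"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        xyz = mol.coords_bohr.copy()
        xyz[1] *= 10.0  # stretch one O-H arm to ~10x
        e, _ = bend_energy(xyz, terms)
        assert abs(e) < 1e-10

    def test_restoring_toward_reference(self, molecules, table):
        mol = molecules["water"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        (i, j, k, c0, kt, r01, r02) = terms.angles[0]
        e_ref, _ = bend_energy(mol.coords_bohr, terms)
        # opening the angle far from theta0 must cost energy
        xyz = mol.coords_bohr.copy()
        rot = np.array([[-1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        xyz[2] = rot @ xyz[2]
        e_far, _ = bend_energy(xyz, terms)
        assert e_far > e_ref


class TestTorsion:
    def test_ethane_staggered_below_eclipsed(self, molecules, table):
        mol = molecules["ethane"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e_stag, g = torsion_energy(mol.coords_bohr, terms)
        # eclipse by rotating one methyl 60 degrees about z (the C-C axis)
        th = math.pi / 3.0
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        xyz = mol.coords_bohr.copy()
        for h in (5, 6, 7):  # hydrogens of the second methyl
            xyz[h] = rot @ xyz[h]
        e_ecl, _ = torsion_energy(xyz, terms)
        assert e_ecl > e_stag
        # staggered geometry is the profile minimum: torque-free
        assert np.abs(g).max() < 1e-8

    def test_ethane_barrier_is_2k_per_torsion(self, molecules, table):
        mol = molecules["ethane"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e_stag, _ = torsion_energy(mol.coords_bohr, terms)
        th = math.pi / 3.0
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        xyz = mol.coords_bohr.copy()
        for h in (5, 6, 7):
            xyz[h] = rot @ xyz[h]
        e_ecl, _ = torsion_energy(xyz, terms)
        # barrier = sum over the 9 H-C-C-H torsions of 2 k_phi (damped);
        # compare against the per-term prediction at the fixture geometry
        i, j, k, l, n, k_phi, *_ = terms.torsions[0]
        assert e_ecl - e_stag > 9 * 2.0 * k_phi * 0.1  # damping keeps >10%

    def test_planar_ethylene_minimum_twisted_maximum(self, molecules, table):
        mol = molecules["ethylene"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e_planar, _ = torsion_energy(mol.coords_bohr, terms)
        th = math.pi / 2.0
        rot = np.array(
            [[1, 0, 0], [0, math.cos(th), -math.sin(th)], [0, math.sin(th), math.cos(th)]]
        )
        xyz = mol.coords_bohr.copy()
        for h in (4, 5):  # hydrogens on the second carbon
            xyz[h] = rot @ xyz[h]
        e_twist, _ = torsion_energy(xyz, terms)
        assert e_twist > e_planar + 0.01  # pi barrier

    def test_collinear_arm_vanishes_smoothly(self, table):
        # make the i-j-k arm collinear: contribution ~ 0, gradient finite
        mol = Molecule(
            [6, 6, 6, 1],
            [[0, 0, 0], [1.45, 0, 0], [2.9, 0, 0], [3.4, 1.0, 0]],
        )
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e, g = torsion_energy(mol.coords_bohr, terms)
        assert abs(e) < 1e-10
        assert np.all(np.isfinite(g))


class TestRepulsion:
    def test_positive_and_monotone(self, table):
        mol, topo, terms = diatomic_terms(table)
        rs = np.array([0.8, 1.2, 1.6, 2.4, 4.8]) * BOHR_PER_ANGSTROM
        es = []
        for r in rs:
            e, _ = bonded_repulsion(np.array([[0, 0, 0], [r, 0, 0]]), terms)
            es.append(e)
        assert all(e > 0 for e in es)
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_short_range_wall(self, table):
        mol, topo, terms = diatomic_terms(table)
        e_tiny, _ = bonded_repulsion(np.array([[0, 0, 0], [1e-4, 0, 0]]), terms)
        assert e_tiny > 1e3  # Coulomb-like divergence


class TestThreeBody:
    def test_no_triples_for_diatomic(self, table):
        mol, topo, terms = diatomic_terms(table)
        e, g = threebody_correction(mol.coords_bohr, terms)
        assert e == 0.0 and np.abs(g).max() == 0.0

    def test_water_has_one_triple(self, molecules, table):
        topo = perceive_topology(molecules["water"], table)
        terms = assemble_covalent_terms(molecules["water"], topo, table)
        assert len(terms.triples) == 1
        e, _ = threebody_correction(molecules["water"].coords_bohr, terms)
        assert e < 0.0  # stabilizing by construction

    def test_bond_stretch_kills_triple(self, molecules, table):
        mol = molecules["water"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        xyz = mol.coords_bohr.copy()
        xyz[1] *= 10.0
        e, _ = threebody_correction(xyz, terms)
        assert abs(e) < 1e-12


class TestGradientsAndInvariance:
    @pytest.mark.parametrize(
        "name", ["water", "ammonia", "ethane", "ethylene", "benzene"]
    )
    def test_analytic_gradient_matches_fd(self, molecules, table, name):
        mol = molecules[name]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        rng = np.random.default_rng(42)
        xyz = mol.coords_bohr + 0.05 * rng.standard_normal((mol.n_atoms, 3))
        for fn in (bond_energy, bend_energy, torsion_energy,
                   bonded_repulsion, threebody_correction):
            arg = terms.bonds if fn is bond_energy else terms
            _, g = fn(xyz, arg)
            gfd = fd_gradient(lambda x: fn(x, arg)[0], xyz)
            assert np.abs(g - gfd).max() < 1e-7

    def test_rigid_motion_invariance(self, molecules, table):
        mol = molecules["ethane"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e0, g0 = covalent_energy(mol.coords_bohr, terms)
        th = 0.9
        rot = np.array(
            [[1, 0, 0], [0, math.cos(th), -math.sin(th)], [0, math.sin(th), math.cos(th)]]
        )
        xyz = mol.coords_bohr @ rot.T + np.array([3.0, -2.0, 7.0])
        e1, g1 = covalent_energy(xyz, terms)
        assert sum(e1.values()) == pytest.approx(sum(e0.values()), abs=1e-12)
        # net force and torque vanish
        assert np.abs(g1.sum(axis=0)).max() < 1e-10
        torque = np.cross(xyz, g1).sum(axis=0)
        assert np.abs(torque).max() < 1e-9

    def test_dissociative_contract(self, molecules, table):
        """Moving one water of the dimer 50 A away leaves the covalent
        energy of the rest unchanged to 1e-10."""
        mol = molecules["water_dimer"]
        topo = perceive_topology(mol, table)
        terms = assemble_covalent_terms(mol, topo, table)
        e0, _ = covalent_energy(mol.coords_bohr, terms)
        xyz = mol.coords_bohr.copy()
        xyz[3:] += np.array([50.0, 0.0, 0.0]) * BOHR_PER_ANGSTROM
        e1, _ = covalent_energy(xyz, terms)
        assert abs(sum(e1.values()) - sum(e0.values())) < 1e-10
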