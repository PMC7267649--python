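import numpy as np
import pytest

from conftest import fd_gradient
from genff.charges import coulomb_kernel
from genff.constants import BOHR_PER_ANGSTROM
from genff.energy_nci import (
    build_pair_list,
    dispersion_coefficients,
    dispersion_energy,
    dispersion_pair_energy,
    electrostatic_energy,
    enumerate_hb_terms,
    hbond_xbond_energy,
    nci_repulsion,
    zeta,
)
from genff.io import Molecule
from genff.topology import perceive_topology


class TestPairList:
    def test_exclusions(self, molecules, table):
        mol = molecules["ethane"]
        topo = perceive_topology(mol, table)
        pairs = build_pair_list(mol, topo, table)
        pset = {(i, j): s for i, j, s in zip(pairs.i, pairs.j, pairs.scale)}
        assert (0, 1) not in pset  # bonded C-C
        assert (0, 2) not in pset  # 1,3 C-H
        assert pset[(2, 5)] == table.globals.scale_14  # H...H across the C-C
        assert len(pairs) <= mol.n_atoms * (mol.n_atoms - 1) // 2

    def test_disconnected_atoms_full_strength(self, molecules, table):
        mol = molecules["helium_dimer"]
        topo = perceive_topology(mol, table)
        pairs = build_pair_list(mol, topo, table)
        assert len(pairs) == 1 and pairs.scale[0] == 1.0


class TestElectrostatics:
    def test_neutral_homonuclear_zero(self, table):
        mol = Molecule([17, 17], [[0, 0, 0], [2.0, 0, 0]])
        topo = perceive_topology(mol, table)
        e, g, q_geom, qm = electrostatic_energy(mol, topo, table)
        assert q_geom == pytest.approx([0.0, 0.0], abs=1e-12)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_asymptotic_coulomb_limit(self):
        gamma = np.array(3.0)
        r = 50.0
        assert coulomb_kernel(np.array(r), gamma) * r == pytest.approx(
            1.0, abs=1e-9
        )

    def test_finite_at_contact(self):
        gamma = np.array(3.0)
        assert coulomb_kernel(np.array(0.0), gamma) == pytest.approx(
            2.0 / (gamma * np.sqrt(np.pi))
        )

    @pytest.mark.parametrize("name", ["water", "hf_dimer", "nacl"])
    def test_gradient_includes_charge_response(
        self, molecules, topologies, table, name
    ):
        mol = molecules[name]
        topo = topologies[name]
        rng = np.random.default_rng(1)
        xyz = mol.coords_bohr + 0.04 * rng.standard_normal((mol.n_atoms, 3))
        _, g, _, _ = electrostatic_energy(mol, topo, table, xyz)
        gfd = fd_gradient(
            lambda x: electrostatic_energy(mol, topo, table, x)[0], xyz
        )
        assert np.abs(g - gfd).max() < 1e-7


class TestDispersion:
    def test_always_attractive(self, molecules, topologies, table):
        mol = molecules["water_dimer"]
        pairs = build_pair_list(mol, topologies["water_dimer"], table)
        e, _ = dispersion_energy(
            mol.coords_bohr, pairs, mol.atomic_numbers, np.zeros(6), table
        )
        assert e < 0.0

    def test_neutral_limit_uses_reference_c6(self, table):
        zs = [8, 1]
        c6, _, _ = dispersion_coefficients(zs, np.zeros(2), table)
        assert zeta(np.zeros(1))[0] == 1.0
        assert c6[0, 1] == pytest.approx(
            np.sqrt(table[8].c6_ref * table[1].c6_ref)
        )

    def test_zeta_monotone_decreasing(self):
        q = np.linspace(-1.5, 1.5, 31)
        z = zeta(q)
        assert np.all(np.diff(z) <= 1e-12)
        assert z.max() <= 3.0

    def test_undamped_asymptote(self, table):
        """At 100 Bohr the BJ damping is negligible: the kernel reduces to
        the plain -s6 C6/r^6 - s8 C8/r^8 sum, and the r^-6 channel alone
        matches -s6 C6/r^6 to 0.1%."""
        g = table.globals
        c6, c8 = 40.0, 900.0
        r0 = np.sqrt(c8 / c6)
        r = 100.0
        e, _ = dispersion_pair_energy(r, c6, c8, r0, table)
        undamped = -g.s6 * c6 / r**6 - g.s8 * c8 / r**8
        assert 0.999 <= e / undamped <= 1.001
        e6, _ = dispersion_pair_energy(r, c6, 0.0, r0, table)
        assert 0.999 <= e6 / (-g.s6 * c6 / r**6) <= 1.001

    def test_anion_gains_cation_loses(self, table):
        zs = [17, 17]
        c6_neg, _, _ = dispersion_coefficients(zs, np.array([-0.5, -0.5]), table)
        c6_pos, _, _ = dispersion_coefficients(zs, np.array([0.5, 0.5]), table)
        c6_neu, _, _ = dispersion_coefficients(zs, np.zeros(2), table)
        assert c6_neg[0, 1] > c6_neu[0, 1] > c6_pos[0, 1]


class TestRepulsionAndCutoffs:
    def test_positive_inside_cutoff(self, molecules, topologies, table):
        mol = molecules["water_dimer"]
        pairs = build_pair_list(mol, topologies["water_dimer"], table)
        e, _ = nci_repulsion(mol.coords_bohr, pairs, mol.atomic_numbers, table)
        assert e > 0.0

    def test_exactly_zero_at_cutoff(self, molecules, topologies, table):
        mol = molecules["helium_dimer"]
        pairs = build_pair_list(mol, topologies["helium_dimer"], table)
        rc = table.globals.cut_rep
        xyz = np.array([[0.0, 0.0, 0.0], [rc, 0.0, 0.0]])
        e, g = nci_repulsion(xyz, pairs, mol.atomic_numbers, table)
        assert e == 0.0
        assert np.abs(g).max() == 0.0

    def test_smooth_across_cutoffs(self, molecules, topologies, table):
        """Dissociation scan in 0.001-Bohr steps crosses the repulsion and
        dispersion cutoffs without any energy discontinuity > 1e-10."""
        mol = molecules["helium_dimer"]
        topo = topologies["helium_dimer"]
        pairs = build_pair_list(mol, topo, table)
        for rc in (table.globals.cut_rep, table.globals.cut_disp):
            rs = np.arange(rc - 0.01, rc + 0.01, 0.001)
            es = []
            for r in rs:
                xyz = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
                e1, _ = nci_repulsion(xyz, pairs, mol.atomic_numbers, table)
                e2, _ = dispersion_energy(
                    xyz, pairs, mol.atomic_numbers, np.zeros(2), table
                )
                es.append(e1 + e2)
            assert np.abs(np.diff(es)).max() < 1e-10

    def test_helium_dimer_single_finite_minimum(self, molecules, topologies, table):
        """Scanned NCI curve (repulsion + dispersion) has one bound minimum."""
        mol = molecules["helium_dimer"]
        pairs = build_pair_list(mol, topologies["helium_dimer"], table)
        rs = np.arange(2.0, 20.0, 0.02)
        es = []
        for r in rs:
            xyz = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
            e1, _ = nci_repulsion(xyz, pairs, mol.atomic_numbers, table)
            e2, _ = dispersion_energy(
                xyz, pairs, mol.atomic_numbers, np.zeros(2), table
            )
            es.append(e1 + e2)
        es = np.array(es)
        k = int(np.argmin(es))
        assert 0 < k < len(es) - 1 and es[k] < 0.0
        # single interior stationary point on the scan
        assert int(np.sum(np.diff(np.sign(np.diff(es))) != 0)) == 1


class TestHydrogenBonds:
    def test_water_dimer_attractive(self, molecules, topologies, forcefields):
        ff = forcefields["water_dimer"]
        e_hb, e_xb, _ = hbond_xbond_energy(
            molecules["water_dimer"].coords_bohr, ff.hb_terms, ff.xb_terms, ff.table
        )
        assert e_hb < 0.0
        assert e_xb == 0.0  # no halogen donors present

    def test_angular_clip_at_85_degrees(self, molecules, table):
        """Bent donor geometry (A-H...B angle < 90 deg) gets no HB energy."""
        mol = molecules["water_dimer"]
        topo = perceive_topology(mol, table)
        hb, xb = enumerate_hb_terms(mol, topo, table)
        # construct: put acceptor O so that the O-H...O angle is 85 deg
        xyz = mol.coords_bohr.copy()
        term = [t for t in hb if t.h == 4][0]  # the on-axis donor H
        a, h, b = term.a, term.h, term.b
        u = xyz[a] - xyz[h]
        u /= np.linalg.norm(u)
        v = np.array([u[1], -u[0], 0.0])
        v /= np.linalg.norm(v)
        direction = np.cos(np.radians(85.0)) * u + np.sin(np.radians(85.0)) * v
        xyz[b] = xyz[h] + 3.5 * direction
        e, _, = _single_term_energy(xyz, term, table)
        assert e == 0.0

    def test_lone_pair_exclusion_zero_along_existing_bond(
        self, molecules, table
    ):
        """Approach collinear with an acceptor's covalent bond is excluded."""
        mol = molecules["water_dimer"]
        topo = perceive_topology(mol, table)
        hb, _ = enumerate_hb_terms(mol, topo, table)
        term = [t for t in hb if t.h == 4][0]
        xyz = mol.coords_bohr.copy()
        # place the donor H exactly along the acceptor O -> H_acc bond
        b = term.b
        neigh = term.lp_neighbors[0]
        u = xyz[neigh] - xyz[b]
        u /= np.linalg.norm(u)
        xyz[term.h] = xyz[b] + 3.5 * u
        xyz[term.a] = xyz[term.h] + 1.8 * u  # keep A-H...B near-linear
        e, _ = _single_term_energy(xyz, term, table)
        assert e == pytest.approx(0.0, abs=1e-20)

    def test_gradient_matches_fd(self, molecules, topologies, forcefields):
        mol = molecules["water_dimer"]
        ff = forcefields["water_dimer"]
        rng = np.random.default_rng(9)
        xyz = mol.coords_bohr + 0.05 * rng.standard_normal((6, 3))
        _, _, g = hbond_xbond_energy(xyz, ff.hb_terms, ff.xb_terms, ff.table)
        gfd = fd_gradient(
            lambda x: sum(
                hbond_xbond_energy(x, ff.hb_terms, ff.xb_terms, ff.table)[:2]
            ),
            xyz,
        )
        assert np.abs(g - gfd).max() < 1e-7

    def test_halogen_bond_enumerated_and_attractive(self, table):
        # CH3Cl ... ammonia arranged for a linear C-Cl...N contact
        mol = Molecule(
            [6, 1, 1, 1, 17, 7, 1, 1, 1],
            [
                [0.0, 0.0, 0.0],
                [0.63, 0.89, 0.0],
                [0.63, -0.45, 0.77],
                [0.63, -0.45, -0.77],
                [-1.78, 0.0, 0.0],
                [-4.9, 0.0, 0.0],
                [-5.3, 0.53, 0.76],
                [-5.3, 0.53, -0.76],
                [-5.3, -0.93, 0.0],
            ],
        )
        topo = perceive_topology(mol, table)
        hb, xb = enumerate_hb_terms(mol, topo, table)
        assert any(t.h == 4 and t.b == 5 for t in xb)
        e_hb, e_xb, _ = hbond_xbond_energy(mol.coords_bohr, hb, xb, table)
        assert e_xb < 0.0


def _single_term_energy(xyz, term, table):
    from genff.energy_nci import _hb_sum

    return _hb_sum(xyz, [term], table.globals.cut_hb)


class TestNewtonThirdLaw:
    def test_net_force_and_torque_zero(self, molecules, forcefields):
        mol = molecules["water_dimer"]
        ff = forcefields["water_dimer"]
        rng = np.random.default_rng(4)
        xyz = mol.coords_bohr + 0.03 * rng.standard_normal((6, 3))
        _, g = ff.energy_gradient(xyz)
        assert np.abs(g.sum(axis=0)).max() < 1e-10
        torque = np.cross(xyz, g).sum(axis=0)
        assert np.abs(torque).max() < 1e-9

    def test_quadratic_pair_count(self, table):
        """Evaluated pair interactions stay below c * N^2 as the system is
        replicated (the quadratic-scaling contract, by counters)."""
        from genff.analysis import generate_fixture
        from genff.engine import ForceField

        base = generate_fixture("water")
        counts, sizes = [], []
        for rep in (1, 2, 4, 8):
            zs = np.tile(base.atomic_numbers, rep)
            xyz = np.concatenate(
                [base.coords + np.array([6.0 * k, 0, 0]) for k in range(rep)]
            )
            mol = Molecule(zs, xyz)
            ff = ForceField(mol, table)
            ff.pair_evaluations = 0
            ff.energy_gradient(mol.coords_bohr)
            counts.append(ff.pair_evaluations)
            sizes.append(mol.n_atoms)
        c0 = counts[0] / sizes[0] ** 2
        for cnt, n in zip(counts, sizes):
            assert cnt <= 3.0 * max(c0, 1.0) * n**2
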