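"""Bonded (covalent) energy terms.

Five contributions: a dissociative Gaussian bond stretch, a cosine-space
angle bend, a cosine-polynomial torsion, a bonded repulsion wall, and a
three-body bond-bond correction.  All terms vanish smoothly on dissociation
of any involved bond (logistic or Gaussian damping), which makes the force
field dissociative: separating a fragment to infinity leaves the remaining
covalent energy exactly unchanged.

Everything here works in atomic units (Bohr/Hartree) on precomputed term
lists frozen at topology-perception time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import cos_angle, cos_dihedral, distance, sin2_angle_from_bonds
from .constants import BOHR_PER_ANGSTROM
from .io import Molecule
from .params import ParameterTable
from .topology import Topology

DEG = math.pi / 180.0

# reference cos(theta0) per central-atom hybridization
_COS_THETA0 = {
    "sp3": math.cos(109.47122063449069 * DEG),
    "sp2": math.cos(120.0 * DEG),
    "sp": -1.0,
    "other": math.cos(109.47122063449069 * DEG),
}


@dataclass
class BondTermParams:
    """Per-bond stretch parameters in atomic units."""

    i: np.ndarray
    j: np.ndarray
    k_b: np.ndarray       # well depth, Hartree
    alpha_b: np.ndarray   # Gaussian width, Bohr^-2
    r0: np.ndarray        # reference length, Bohr

    def __len__(self):
        return len(self.i)


@dataclass
class CovalentTerms:
    """All frozen bonded term lists for one molecule."""

    bonds: BondTermParams
    # angles: (i, j, k, cos_theta0, k_theta, r0_ij, r0_jk)
    angles: list = field(default_factory=list)
    # torsions: (i, j, k, l, n, k_phi, r0_ij, r0_jk, r0_kl)
    torsions: list = field(default_factory=list)
    # rep pairs: (i, j, zz, a_rep) over bonded pairs
    rep_pairs: list = field(default_factory=list)
    # triples: (a, b, c, bond_idx_ab, bond_idx_bc)
    triples: list = field(default_factory=list)
    k3: float = 0.02
    damp_k: float = 8.0
    damp_s: float = 1.5


def assemble_bond_params(
    mol: Molecule, topo: Topology, table: ParameterTable
) -> BondTermParams:
    """k_b from geometric-mean well depths scaled by bond order, alpha from
    arithmetic-mean widths, r0 from the perceived topology (Angstrom->Bohr).

    For pi bonds the well deepens with bond order (k_b ~ BO^p) while r0
    contracts (logarithmic term applied at perception time), so force
    constants follow the Hueckel bond orders.
    """
    zs = mol.atomic_numbers
    g = table.globals
    i_, j_, kb, ab, r0 = [], [], [], [], []
    for b in topo.bonds:
        zi, zj = int(zs[b.i]), int(zs[b.j])
        i_.append(b.i)
        j_.append(b.j)
        kb.append(table.pair_k_bond(zi, zj) * b.bond_order**g.p_bo)
        ab.append(table.pair_alpha_bond(zi, zj))
        r0.append(b.r0 * BOHR_PER_ANGSTROM)
    return BondTermParams(
        np.array(i_, dtype=int),
        np.array(j_, dtype=int),
        np.array(kb),
        np.array(ab),
        np.array(r0),
    )


def _ring_theta0(topo: Topology, i: int, j: int, k: int):
    """Small-ring override: 60 deg in 3-rings, 90 deg in 4-rings."""
    for ring in topo.rings:
        if len(ring) in (3, 4) and i in ring and j in ring and k in ring:
            return math.cos((60.0 if len(ring) == 3 else 90.0) * DEG)
    return None


def assemble_covalent_terms(
    mol: Molecule, topo: Topology, table: ParameterTable
) -> CovalentTerms:
    zs = mol.atomic_numbers
    g = table.globals
    bonds = assemble_bond_params(mol, topo, table)
    r0_map = {}
    bidx = {}
    for t, b in enumerate(topo.bonds):
        r0_map[(b.i, b.j)] = bonds.r0[t]
        r0_map[(b.j, b.i)] = bonds.r0[t]
        bidx[(b.i, b.j)] = t
        bidx[(b.j, b.i)] = t

    angles = []
    for i, j, k in topo.angles:
        c0 = _ring_theta0(topo, i, j, k)
        if c0 is None:
            c0 = _COS_THETA0[topo.hybridization[j]]
        angles.append(
            (i, j, k, c0, table[int(zs[j])].k_bend, r0_map[(i, j)], r0_map[(j, k)])
        )

    bo_map = {}
    for b in topo.bonds:
        bo_map[(b.i, b.j)] = b.bond_order
        bo_map[(b.j, b.i)] = b.bond_order
    torsions = []
    for i, j, k, l in topo.torsions:
        bo = bo_map[(j, k)]
        hj, hk = topo.hybridization[j], topo.hybridization[k]
        pi_like = bo > 1.2 or (hj in ("sp2", "sp") and hk in ("sp2", "sp"))
        if pi_like:
            n, k_phi = 2, g.k_tors_pi * max(bo - 1.0, 0.2)
        else:
            n = 3
            k_phi = math.sqrt(table[int(zs[j])].k_tors * table[int(zs[k])].k_tors)
        torsions.append(
            (i, j, k, l, n, k_phi, r0_map[(i, j)], r0_map[(j, k)], r0_map[(k, l)])
        )

    rep_pairs = []
    for b in topo.bonds:
        zi, zj = int(zs[b.i]), int(zs[b.j])
        rep_pairs.append(
            (
                b.i,
                b.j,
                table[zi].z_rep * table[zj].z_rep,
                table.pair_alpha_rep(zi, zj),
            )
        )

    triples = []
    for i, j, k in topo.angles:  # j central: bonds (i,j) and (j,k)
        triples.append((i, j, k, bidx[(i, j)], bidx[(j, k)]))

    return CovalentTerms(
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        rep_pairs=rep_pairs,
        triples=triples,
        k3=g.k3,
        damp_k=g.k_damp,
        damp_s=g.s_damp,
    )


# ---------------------------------------------------------------------------
# term evaluators: each returns (E, grad) with grad shaped (N, 3)
# ---------------------------------------------------------------------------


def _damp(r: float, r0: float, k: float, s: float):
    """Logistic bond-length damping, ~1 at r0, -> 0 on dissociation."""
    x = k * (r / r0 - s)
    if x > 500.0:
        return 0.0, 0.0
    e = math.exp(x)
    d = 1.0 / (1.0 + e)
    ddr = -d * d * e * k / r0
    return d, ddr


def bond_energy(xyz: np.ndarray, bonds: BondTermParams):
    """E = -sum k_b exp(-alpha_b (r - r0)^2): a dissociative Gaussian well.

    Minimum -k_b at r = r0; second derivative there is 2 k_b alpha_b (the
    harmonic force constant); E -> 0 for r -> infinity, allowing cleavage.
    """
    n = xyz.shape[0]
    grad = np.zeros((n, 3))
    if len(bonds) == 0:
        return 0.0, grad
    d = xyz[bonds.i] - xyz[bonds.j]
    r = np.sqrt((d**2).sum(1))
    dr = r - bonds.r0
    arg = bonds.alpha_b * dr**2
    e = -bonds.k_b * np.exp(-np.minimum(arg, 700.0))
    dedr = -2.0 * bonds.alpha_b * dr * e
    gpair = (dedr / r)[:, None] * d
    np.add.at(grad, bonds.i, gpair)
    np.add.at(grad, bonds.j, -gpair)
    return float(e.sum()), grad


def bonded_repulsion(xyz: np.ndarray, terms: CovalentTerms):
    """E = sum z_i z_j / r * exp(-sqrt(a_i a_j) r^1.5) over bonded pairs."""
    n = xyz.shape[0]
    grad = np.zeros((n, 3))
    e_tot = 0.0
    for i, j, zz, a in terms.rep_pairs:
        r, u = distance(xyz, i, j)
        e = zz / r * math.exp(-a * r**1.5)
        dedr = -e * (1.0 / r + 1.5 * a * math.sqrt(r))
        e_tot += e
        grad[i] += dedr * u
        grad[j] -= dedr * u
    return e_tot, grad


def bend_energy(xyz: np.ndarray, terms: CovalentTerms):
    """E = sum k_theta d(r_ij) d(r_jk) (cos theta0 - cos theta)^2.

    The cosine formulation is nonsingular at theta = 180 deg; the logistic
    bond damping removes the term smoothly when either arm dissociates.
    """
    n = xyz.shape[0]
    grad = np.zeros((n, 3))
    e_tot = 0.0
    dk, ds = terms.damp_k, terms.damp_s
    for i, j, k, c0, kt, r01, r02 in terms.angles:
        r1, u1 = distance(xyz, i, j)
        r2, u2 = distance(xyz, k, j)
        d1, dd1 = _damp(r1, r01, dk, ds)
        d2, dd2 = _damp(r2, r02, dk, ds)
        if d1 == 0.0 and d2 == 0.0:
            continue
        c, gi, gj, gk = cos_angle(xyz, i, j, k)
        diff = c0 - c
        e = kt * d1 * d2 * diff * diff
        e_tot += e
        pref = -2.0 * kt * d1 * d2 * diff  # dE/dc
        grad[i] += pref * gi
        grad[j] += pref * gj
        grad[k] += pref * gk
        # damping chain: dE/dr1, dE/dr2
        gdr1 = kt * dd1 * d2 * diff * diff
        gdr2 = kt * d1 * dd2 * diff * diff
        grad[i] += gdr1 * u1
        grad[j] -= gdr1 * u1
        grad[k] += gdr2 * u2
        grad[j] -= gdr2 * u2
    return e_tot, grad


def _torsion_profile(c: float, n: int):
    """1 + cos(n phi - phi0) expressed in c = cos(phi), with d/dc.

    n = 3 uses phi0 = 0 (staggered sp3-sp3 minimum at phi = 60 deg),
    n = 2 uses phi0 = 180 deg (planar minimum for pi bonds).
    """
    if n == 3:
        # 1 + cos(3 phi) = 1 + 4 c^3 - 3 c
        return 1.0 + 4.0 * c**3 - 3.0 * c, 12.0 * c**2 - 3.0
    if n == 2:
        # 1 - cos(2 phi) = 2 (1 - c^2)
        return 2.0 * (1.0 - c * c), -4.0 * c
    raise ValueError(f"unsupported torsion multiplicity {n}")


def torsion_energy(xyz: np.ndarray, terms: CovalentTerms):
    """E = sum k_phi * damp(3 bonds) * sin^2(t1) sin^2(t2) * profile(cos phi).

    The sin^2 factors of the flanking angles remove the dihedral singularity
    at collinear arms; the logistic factors dissociate the term with any of
    the three involved bonds.
    """
    n_at = xyz.shape[0]
    grad = np.zeros((n_at, 3))
    e_tot = 0.0
    dk, ds = terms.damp_k, terms.damp_s
    for i, j, k, l, n, k_phi, r01, r02, r03 in terms.torsions:
        r1, u1 = distance(xyz, i, j)
        r2, u2 = distance(xyz, j, k)
        r3, u3 = distance(xyz, k, l)
        d1, dd1 = _damp(r1, r01, dk, ds)
        d2, dd2 = _damp(r2, r02, dk, ds)
        d3, dd3 = _damp(r3, r03, dk, ds)
        ddd = d1 * d2 * d3
        if ddd == 0.0:
            continue
        s1, s1_i, s1_j, s1_k = sin2_angle_from_bonds(xyz, i, j, k)
        s2, s2_j, s2_k, s2_l = sin2_angle_from_bonds(xyz, j, k, l)
        if s1 < 1e-12 or s2 < 1e-12:
            continue
        c, (ci, cj, ck, cl), ok = cos_dihedral(xyz, i, j, k, l)
        if not ok:
            continue
        prof, dprof = _torsion_profile(c, n)
        base = k_phi * ddd
        e = base * s1 * s2 * prof
        e_tot += e
        # d/dc
        pc = base * s1 * s2 * dprof
        grad[i] += pc * ci
        grad[j] += pc * cj
        grad[k] += pc * ck
        grad[l] += pc * cl
        # d/ds1, d/ds2
        p1 = base * s2 * prof
        grad[i] += p1 * s1_i
        grad[j] += p1 * s1_j
        grad[k] += p1 * s1_k
        p2 = base * s1 * prof
        grad[j] += p2 * s2_j
        grad[k] += p2 * s2_k
        grad[l] += p2 * s2_l
        # damping chains
        rest = k_phi * s1 * s2 * prof
        g1 = rest * dd1 * d2 * d3
        grad[i] += g1 * u1
        grad[j] -= g1 * u1
        g2 = rest * d1 * dd2 * d3
        grad[j] += g2 * u2
        grad[k] -= g2 * u2
        g3 = rest * d1 * d2 * dd3
        grad[k] += g3 * u3
        grad[l] -= g3 * u3
    return e_tot, grad


def threebody_correction(xyz: np.ndarray, terms: CovalentTerms):
    """Stabilizing bond-bond coupling over triples sharing a central atom:

    E = -k3 sum k_AB k_BC exp(-a_AB dAB^2) exp(-a_BC dBC^2) cos^2(theta_ABC)

    Gaussian factors reuse the stretch-term well shapes, so the correction
    vanishes whenever either participating bond dissociates.
    """
    n = xyz.shape[0]
    grad = np.zeros((n, 3))
    e_tot = 0.0
    b = terms.bonds
    for a_, c_, e_, t1, t2 in terms.triples:
        i, j, k = a_, c_, e_  # i-j and j-k bonded, j central
        r1, u1 = distance(xyz, i, j)
        r2, u2 = distance(xyz, k, j)
        dr1 = r1 - b.r0[t1]
        dr2 = r2 - b.r0[t2]
        g1 = math.exp(-min(b.alpha_b[t1] * dr1 * dr1, 700.0))
        g2 = math.exp(-min(b.alpha_b[t2] * dr2 * dr2, 700.0))
        if g1 * g2 < 1e-300:
            continue
        c, gi, gj, gk = cos_angle(xyz, i, j, k)
        pref = -terms.k3 * b.k_b[t1] * b.k_b[t2]
        e = pref * g1 * g2 * c * c
        e_tot += e
        # distance chains
        de_dr1 = pref * (-2.0 * b.alpha_b[t1] * dr1) * g1 * g2 * c * c
        de_dr2 = pref * g1 * (-2.0 * b.alpha_b[t2] * dr2) * g2 * c * c
        grad[i] += de_dr1 * u1
        grad[j] -= de_dr1 * u1
        grad[k] += de_dr2 * u2
        grad[j] -= de_dr2 * u2
        # angle chain
        dc = pref * g1 * g2 * 2.0 * c
        grad[i] += dc * gi
        grad[j] += dc * gj
        grad[k] += dc * gk
    return e_tot, grad


def covalent_energy(xyz: np.ndarray, terms: CovalentTerms):
    """All five bonded contributions; returns (dict of terms, grad)."""
    e_bond, g_bond = bond_energy(xyz, terms.bonds)
    e_bend, g_bend = bend_energy(xyz, terms)
    e_tors, g_tors = torsion_energy(xyz, terms)
    e_rep, g_rep = bonded_repulsion(xyz, terms)
    e_abc, g_abc = threebody_correction(xyz, terms)
    grad = g_bond + g_bend + g_tors + g_rep + g_abc
    return (
        {
            "e_bond": e_bond,
            "e_bend": e_bend,
            "e_tors": e_tors,
            "e_rep_bond": e_rep,
            "e_abc": e_abc,
        },
        grad,
    )
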