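"""Non-covalent energy terms.

Five contributions: EEQ electrostatics over *all* pairs (the model carries
the entire electrostatic energy, bonded pairs included), charge-scaled
two-term dispersion with Becke-Johnson rational damping, directional
hydrogen- and halogen-bond corrections with a lone-pair exclusion factor,
and a non-bonded repulsion wall.

Charge handling: the electrostatic energy is evaluated at the mixture
q = (q_geom + q_topo)/2 of the geometry-dependent and the bond-topology EEQ
sets; its gradient carries the exact linear-response term of q_geom (one
extra solve with the already-factorized EEQ matrix) while q_topo is constant
by construction.  Dispersion and HB/XB strengths are scaled by the topology
charge set only, so their pair coefficients are geometric constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._geom import cos_angle, distance, sin2_angle_from_bonds
from .charges import (
    chi_effective,
    coulomb_kernel,
    coulomb_kernel_deriv,
    _gamma_matrix,
    _solve_bordered,
)
from .constants import BOHR_PER_ANGSTROM
from .io import Molecule
from .params import ParameterTable
from .topology import Topology, coordination_numbers_with_derivs

HB_ELEMENTS = {7, 8, 9, 16, 17}
XB_DONORS = {17, 35, 53}


@dataclass
class NciPairList:
    """Non-bonded pairs with exclusion-derived scale factors.

    1,2 and 1,3 pairs (bonded, or sharing a bond partner) are excluded;
    1,4 pairs are scaled by the global factor; everything else is full
    strength.  Derived solely from the frozen topology.
    """

    i: np.ndarray
    j: np.ndarray
    scale: np.ndarray
    n_atoms: int = 0

    def __len__(self):
        return len(self.i)


def build_pair_list(mol: Molecule, topo: Topology, table: ParameterTable) -> NciPairList:
    n = mol.n_atoms
    if topo.bonds:
        rows = [b.i for b in topo.bonds] + [b.j for b in topo.bonds]
        cols = [b.j for b in topo.bonds] + [b.i for b in topo.bonds]
        g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        hops = shortest_path(g, directed=False, unweighted=True)
    else:
        hops = np.full((n, n), np.inf)
    ii, jj, sc = [], [], []
    s14 = table.globals.scale_14
    for i in range(n):
        for j in range(i + 1, n):
            h = hops[i, j]
            if h <= 2:
                continue
            ii.append(i)
            jj.append(j)
            sc.append(s14 if h == 3 else 1.0)
    return NciPairList(np.array(ii, int), np.array(jj, int), np.array(sc), n)


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------


def electrostatic_energy(
    mol: Molecule,
    topo: Topology,
    table: ParameterTable,
    xyz: np.ndarray | None = None,
    q_topo: np.ndarray | None = None,
):
    """EEQ electrostatic energy and its exact gradient.

    Returns (E, grad, q_geom, q_mixed).  ``xyz`` in Bohr.
    """
    zs = mol.atomic_numbers
    n = mol.n_atoms
    if xyz is None:
        xyz = mol.coords_bohr
    if q_topo is None:
        q_topo = topo.topo_charges
    grad = np.zeros((n, 3))

    eta = np.array([table[int(z)].eta for z in zs])
    ccn = np.array([table[int(z)].c_cn for z in zs])
    gamma = _gamma_matrix(zs, table)

    dvec = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((dvec**2).sum(-1))
    np.fill_diagonal(r, 1.0)

    cn, dfdr_a = coordination_numbers_with_derivs(
        xyz / BOHR_PER_ANGSTROM, zs, table
    )
    dfdr = dfdr_a / BOHR_PER_ANGSTROM  # now per Bohr
    chi = chi_effective(zs, cn, table)
    dchi_dcn = ccn / (2.0 * np.sqrt(np.maximum(cn, 0.0) + 1e-30))

    a = coulomb_kernel(r, gamma)
    np.fill_diagonal(a, 0.0)
    da = coulomb_kernel_deriv(r, gamma)
    np.fill_diagonal(da, 0.0)

    q_geom, _, factor = _solve_bordered(a, chi, eta, mol.total_charge)
    qm = 0.5 * (q_geom + q_topo)

    e = float(chi @ qm + 0.5 * qm @ (eta * qm) + 0.5 * qm @ (a @ qm))

    # response vector: dE/dq at the mixed charges, through the EEQ solve
    g_q = chi + eta * qm + a @ qm
    w = lu_solve(factor, np.concatenate([g_q, [0.0]]))[:n]

    # per-pair radial coefficients
    pair_c = (np.outer(qm, qm) - 0.5 * (np.outer(w, q_geom) + np.outer(q_geom, w))) * da
    t = (qm - 0.5 * w) * dchi_dcn
    pair_c = pair_c + (t[:, None] + t[None, :]) * dfdr
    np.fill_diagonal(pair_c, 0.0)

    # grad_i = sum_j c_ij * (x_i - x_j)/r_ij   (c symmetric by construction)
    u = dvec / r[:, :, None]
    grad = (pair_c[:, :, None] * u).sum(axis=1)
    return e, grad, q_geom, qm


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def zeta(q: np.ndarray) -> np.ndarray:
    """Charge scaling of C6: monotone decreasing, zeta(0) = 1, capped at 3."""
    return np.minimum(np.exp(3.0 * (1.0 - np.exp(np.minimum(q, 50.0)))), 3.0)


def dispersion_coefficients(zs, q: np.ndarray, table: ParameterTable):
    """Per-pair C6, C8 and critical radius R0 = sqrt(C8/C6)."""
    c6_at = np.array([table[int(z)].c6_ref for z in zs]) * zeta(q)
    qfac = np.array([table[int(z)].alpha_pol for z in zs]) ** (2.0 / 3.0)
    c6 = np.sqrt(np.outer(c6_at, c6_at))
    c8 = 3.0 * c6 * np.sqrt(np.outer(qfac, qfac))
    r0 = np.sqrt(np.where(c6 > 0, c8 / np.where(c6 > 0, c6, 1.0), 9.0))
    return c6, c8, r0


def dispersion_pair_energy(r, c6, c8, r0, table: ParameterTable):
    """Untruncated BJ-damped pair kernel; returns (e, de/dr)."""
    g = table.globals
    rc = g.a1 * r0 + g.a2
    d6 = rc**6
    d8 = rc**8
    e = -g.s6 * c6 / (r**6 + d6) - g.s8 * c8 / (r**8 + d8)
    dedr = (
        g.s6 * c6 * 6.0 * r**5 / (r**6 + d6) ** 2
        + g.s8 * c8 * 8.0 * r**7 / (r**8 + d8) ** 2
    )
    return e, dedr


def dispersion_energy(
    xyz: np.ndarray,
    pairs: NciPairList,
    zs,
    q: np.ndarray,
    table: ParameterTable,
):
    """Pairwise charge-scaled dispersion with shifted-force truncation.

    The energy and its radial derivative both go exactly to zero at the
    cutoff, keeping the total potential C1-smooth.
    """
    n = pairs.n_atoms
    grad = np.zeros((n, 3))
    if len(pairs) == 0:
        return 0.0, grad
    rc_cut = table.globals.cut_disp
    c6m, c8m, r0m = dispersion_coefficients(zs, q, table)
    d = xyz[pairs.i] - xyz[pairs.j]
    r = np.sqrt((d**2).sum(1))
    c6 = c6m[pairs.i, pairs.j]
    c8 = c8m[pairs.i, pairs.j]
    r0 = r0m[pairs.i, pairs.j]
    e, dedr = dispersion_pair_energy(r, c6, c8, r0, table)
    ec, dec = dispersion_pair_energy(rc_cut, c6, c8, r0, table)
    inside = r < rc_cut
    e_sf = np.where(inside, (e - ec - (r - rc_cut) * dec) * pairs.scale, 0.0)
    dedr_sf = np.where(inside, (dedr - dec) * pairs.scale, 0.0)
    gp = (dedr_sf / r)[:, None] * d
    np.add.at(grad, pairs.i, gp)
    np.add.at(grad, pairs.j, -gp)
    return float(e_sf.sum()), grad


# ---------------------------------------------------------------------------
# non-bonded repulsion
# ---------------------------------------------------------------------------


def nci_repulsion(
    xyz: np.ndarray, pairs: NciPairList, zs, table: ParameterTable
):
    """Same functional family as the bonded wall, independent global scale
    and exponent, shifted-force truncated at the repulsion cutoff."""
    n = pairs.n_atoms
    grad = np.zeros((n, 3))
    if len(pairs) == 0:
        return 0.0, grad
    g = table.globals
    rc = g.cut_rep
    zrep = np.array([table[int(z)].z_rep for z in zs])
    arep = np.array([table[int(z)].alpha_rep for z in zs])
    zz = zrep[pairs.i] * zrep[pairs.j] * g.s_rep_nci
    aa = np.sqrt(arep[pairs.i] * arep[pairs.j]) * g.c_rep_nci
    d = xyz[pairs.i] - xyz[pairs.j]
    r = np.sqrt((d**2).sum(1))

    def kernel(rr):
        e = zz / rr * np.exp(-aa * rr**1.5)
        dedr = -e * (1.0 / rr + 1.5 * aa * np.sqrt(rr))
        return e, dedr

    e, dedr = kernel(r)
    ec, dec = kernel(np.full_like(r, rc))
    inside = r < rc
    e_sf = np.where(inside, (e - ec - (r - rc) * dec) * pairs.scale, 0.0)
    dedr_sf = np.where(inside, (dedr - dec) * pairs.scale, 0.0)
    gp = (dedr_sf / r)[:, None] * d
    np.add.at(grad, pairs.i, gp)
    np.add.at(grad, pairs.j, -gp)
    return float(e_sf.sum()), grad


# ---------------------------------------------------------------------------
# hydrogen / halogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HbTerm:
    a: int      # donor heavy atom
    h: int      # bridging hydrogen (or halogen X for XB)
    b: int      # acceptor
    strength: float
    r_ref: float
    width: float
    lp_neighbors: tuple = ()


def enumerate_hb_terms(mol: Molecule, topo: Topology, table: ParameterTable):
    """Donor triples A-H...B and R-X...B from the frozen topology.

    The strength factor carries the element donor/acceptor scales and the
    (topology-)charge dependence g = exp(k_gq (q_H - q_B)): a more positive
    hydrogen and a more negative acceptor strengthen the bond.
    """
    zs = mol.atomic_numbers
    g = table.globals
    q = topo.topo_charges
    rcov = np.array(
        [table[int(z)].r_cov for z in zs]
    ) * BOHR_PER_ANGSTROM
    hb, xb = [], []
    for bnd in topo.bonds:
        for a, h in ((bnd.i, bnd.j), (bnd.j, bnd.i)):
            if int(zs[h]) != 1 or int(zs[a]) not in HB_ELEMENTS:
                continue
            acid = table[int(zs[a])].hb_acid
            if acid == 0.0:
                continue
            for b in range(mol.n_atoms):
                if b in (a, h) or int(zs[b]) not in HB_ELEMENTS:
                    continue
                if b in topo.neighbors[h]:
                    continue
                base = table[int(zs[b])].hb_base
                if base == 0.0:
                    continue
                s = (
                    g.k_hb
                    * acid
                    * base
                    * math.exp(g.k_gq * (q[h] - q[b]))
                )
                lp = tuple(c for c in topo.neighbors[b] if c != h)
                hb.append(
                    HbTerm(
                        a, h, b, s,
                        g.hb_rscale * (rcov[h] + rcov[b]),
                        g.hb_width, lp,
                    )
                )
    for x in range(mol.n_atoms):
        if int(zs[x]) not in XB_DONORS:
            continue
        if len(topo.neighbors[x]) != 1:
            continue  # sigma-hole requires exactly one covalent partner
        rdon = topo.neighbors[x][0]
        strength_x = table[int(zs[x])].xb_str
        if strength_x == 0.0:
            continue
        for b in range(mol.n_atoms):
            if b in (x, rdon) or int(zs[b]) not in HB_ELEMENTS:
                continue
            if b in topo.neighbors[x]:
                continue
            base = table[int(zs[b])].hb_base
            if base == 0.0:
                continue
            s = g.k_xb * strength_x * base * math.exp(g.k_gq * (q[x] - q[b]))
            lp = tuple(c for c in topo.neighbors[b] if c != x)
            xb.append(
                HbTerm(
                    rdon, x, b, s,
                    g.xb_rscale * (rcov[x] + rcov[b]),
                    g.xb_width, lp,
                )
            )
    return hb, xb


def _hb_sum(xyz: np.ndarray, terms: list, cutoff: float):
    """Shared evaluator for HB and XB corrections.

    E = -sum s * f_dist(r_HB) * f_ang(theta_AHB) * prod_C sin^2(C-B-H)

    f_ang = cos^4 clipped to zero for theta < 90 deg; the lone-pair product
    suppresses approach along the acceptor's existing bonds.
    """
    n = xyz.shape[0]
    grad = np.zeros((n, 3))
    e_tot = 0.0
    for t in terms:
        r, u = distance(xyz, t.h, t.b)
        if r > cutoff:
            continue
        fd = math.exp(-t.width * (r - t.r_ref) ** 2)
        dfd = -2.0 * t.width * (r - t.r_ref) * fd
        c, ga, gh, gb = cos_angle(xyz, t.a, t.h, t.b)
        if c >= 0.0:
            continue  # theta < 90 deg: clipped (cos^4 joins with zero slope)
        fa = c**4
        dfa = 4.0 * c**3
        # lone-pair exclusion product
        flp = 1.0
        lp_grads = []
        for catom in t.lp_neighbors:
            s2, gc_, gb_, gh_ = sin2_angle_from_bonds(xyz, catom, t.b, t.h)
            lp_grads.append((catom, s2, gc_, gb_, gh_))
            flp *= s2
        e = -t.strength * fd * fa * flp
        e_tot += e
        # distance chain
        pr = -t.strength * dfd * fa * flp
        grad[t.h] += pr * u
        grad[t.b] -= pr * u
        # angle chain
        pc = -t.strength * fd * dfa * flp
        grad[t.a] += pc * ga
        grad[t.h] += pc * gh
        grad[t.b] += pc * gb
        # lone-pair chains
        for catom, s2, gc_, gb_, gh_ in lp_grads:
            if s2 < 1e-14:
                continue
            ps = e / s2  # derivative of the product with respect to this s2
            grad[catom] += ps * gc_
            grad[t.b] += ps * gb_
            grad[t.h] += ps * gh_
    return e_tot, grad


def hbond_xbond_energy(
    xyz: np.ndarray, hb_terms: list, xb_terms: list, table: ParameterTable
):
    cutoff = table.globals.cut_hb
    e_hb, g_hb = _hb_sum(xyz, hb_terms, cutoff)
    e_xb, g_xb = _hb_sum(xyz, xb_terms, cutoff)
    return e_hb, e_xb, g_hb + g_xb
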