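"""Automatic perception of the covalent topology.

The bonding network is derived once, from covalent radii, and then frozen:
energies and gradients never re-perceive bonds during optimization or
dynamics (the non-reactive contract -- bond *potentials* still dissociate
smoothly).  Besides the bond graph this module enumerates angles, torsions,
small rings (size <= 8), per-atom hybridization, connected fragments, the
pi subsystem and its iterative Hueckel bond orders, and the topology-only
EEQ charge set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Molecule
from .params import ParameterTable, default_table


@dataclass
class Bond:
    i: int
    j: int
    r0: float  # reference length, Angstrom
    bond_order: float = 1.0


@dataclass
class Topology:
    bonds: list
    angles: list
    torsions: list
    rings: list
    hybridization: list
    fragments: np.ndarray
    pi_atoms: list
    pi_systems: list
    cn: np.ndarray
    topo_charges: np.ndarray
    neighbors: list = field(default_factory=list)

    def bond_index(self) -> dict:
        return {(b.i, b.j): b for b in self.bonds}


# ---------------------------------------------------------------------------
# coordination numbers
# ---------------------------------------------------------------------------


def _pair_distances(xyz: np.ndarray):
    d = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((d**2).sum(-1))
    return d, r


def cn_count(r: float, rcov_sum: float, k_cn: float) -> float:
    """Logistic counting function; 0.5 exactly at r = rcov_sum."""
    return 1.0 / (1.0 + np.exp(-k_cn * (rcov_sum / r - 1.0)))


def coordination_numbers(
    mol: Molecule, table: ParameterTable | None = None
) -> np.ndarray:
    table = table or default_table()
    cn, _ = coordination_numbers_with_derivs(
        mol.coords, mol.atomic_numbers, table
    )
    return cn


def coordination_numbers_with_derivs(
    coords_a: np.ndarray, zs: np.ndarray, table: ParameterTable
):
    """CN per atom and the pairwise derivative matrix d f(r_ij)/d r_ij.

    Distances in Angstrom; the derivative matrix is with respect to the
    distance in Angstrom as well (callers convert units).
    """
    n = len(zs)
    k_cn = table.globals.k_cn
    rcov = np.array([table[z].r_cov for z in zs])
    if n == 1:
        return np.zeros(1), np.zeros((1, 1))
    _, r = _pair_distances(np.asarray(coords_a, float))
    np.fill_diagonal(r, np.inf)
    rsum = rcov[:, None] + rcov[None, :]
    x = -k_cn * (rsum / r - 1.0)
    # clip to avoid overflow; the counting function saturates anyway
    f = 1.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0)))
    cn = f.sum(axis=1)
    dfdr = -f * (1.0 - f) * k_cn * rsum / r**2
    np.fill_diagonal(dfdr, 0.0)
    return cn, dfdr


# ---------------------------------------------------------------------------
# bond detection
# ---------------------------------------------------------------------------


def _max_neighbors(z: int) -> int:
    if z <= 2:
        return 2
    if z <= 10:
        return 4
    if (21 <= z <= 30) or (39 <= z <= 48) or (57 <= z <= 80):
        return 8
    return 6


def detect_bonds(mol: Molecule, table: ParameterTable | None = None) -> list:
    """Pairs with r_ij < f_bond * (r_cov,i + r_cov,j), hypervalence-pruned.

    Pruning removes the longest excess bond of an over-coordinated atom
    first; ties break toward the lower (i, j) index pair, which makes the
    result deterministic.
    """
    table = table or default_table()
    zs = mol.atomic_numbers
    n = mol.n_atoms
    rcov = np.array([table[z].r_cov for z in zs])
    _, r = _pair_distances(mol.coords)
    cut = table.globals.f_bond * (rcov[:, None] + rcov[None, :])
    pairs = [
        (i, j) for i in range(n) for j in range(i + 1, n) if r[i, j] < cut[i, j]
    ]
    # hypervalent guard
    neigh = {i: set() for i in range(n)}
    for i, j in pairs:
        neigh[i].add(j)
        neigh[j].add(i)
    alive = set(pairs)
    changed = True
    while changed:
        changed = False
        for a in range(n):
            limit = _max_neighbors(int(zs[a]))
            while len(neigh[a]) > limit:
                cand = sorted(
                    (tuple(sorted((a, b))) for b in neigh[a]),
                    key=lambda p: (-r[p[0], p[1]], p),
                )
                drop = cand[0]
                alive.discard(drop)
                neigh[drop[0]].discard(drop[1])
                neigh[drop[1]].discard(drop[0])
                changed = True
    return sorted(alive)


# ---------------------------------------------------------------------------
# derived lists
# ---------------------------------------------------------------------------


def _neighbor_lists(n: int, pairs: list) -> list:
    neigh = [[] for _ in range(n)]
    for i, j in pairs:
        neigh[i].append(j)
        neigh[j].append(i)
    return [sorted(v) for v in neigh]


def _enumerate_angles(neighbors: list) -> list:
    angles = []
    for j, nb in enumerate(neighbors):
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles


def _enumerate_torsions(pairs: list, neighbors: list) -> list:
    torsions = []
    for j, k in pairs:
        for i in neighbors[j]:
            if i == k:
                continue
            for l in neighbors[k]:
                if l == j or l == i:
                    continue
                torsions.append((i, j, k, l))
    return torsions


def _find_rings(n: int, pairs: list, max_size: int = 8) -> list:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(pairs)
    rings = []
    for cyc in nx.minimum_cycle_basis(g):
        if len(cyc) <= max_size:
            # minimum_cycle_basis returns node sets; recover the cycle order
            sub = g.subgraph(cyc)
            try:
                ordered = nx.cycle_basis(sub)[0]
            except IndexError:
                continue
            k = ordered.index(min(ordered))
            ordered = ordered[k:] + ordered[:k]
            if len(ordered) > 2 and ordered[1] > ordered[-1]:
                ordered = [ordered[0]] + ordered[1:][::-1]
            rings.append(ordered)
    return sorted(rings, key=lambda c: (len(c), c))


def _angle_deg(xyz, i, j, k) -> float:
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _hybridization(mol: Molecule, neighbors: list) -> list:
    """Per-atom sp/sp2/sp3 assignment from neighbor count and geometry."""
    zs = mol.atomic_numbers
    xyz = mol.coords
    out = []
    for a in range(mol.n_atoms):
        z = int(zs[a])
        nb = neighbors[a]
        deg = len(nb)
        hyb = "other"
        if z in (6, 14):  # carbon group
            if deg >= 4:
                hyb = "sp3"
            elif deg == 3:
                s = sum(
                    _angle_deg(xyz, nb[p], a, nb[q])
                    for p in range(3)
                    for q in range(p + 1, 3)
                )
                hyb = "sp2" if s > 348.0 else "sp3"
            elif deg == 2:
                hyb = "sp" if _angle_deg(xyz, nb[0], a, nb[1]) > 160.0 else "sp2"
            elif deg == 1:
                hyb = "sp"  # terminal carbon: nitrile/acetylide-like
        elif z in (7, 15):  # nitrogen group
            if deg >= 4:
                hyb = "sp3"
            elif deg == 3:
                s = sum(
                    _angle_deg(xyz, nb[p], a, nb[q])
                    for p in range(3)
                    for q in range(p + 1, 3)
                )
                hyb = "sp2" if s > 350.0 else "sp3"
            elif deg == 2:
                hyb = "sp" if _angle_deg(xyz, nb[0], a, nb[1]) > 160.0 else "sp2"
            elif deg == 1:
                hyb = "sp"
        elif z in (8, 16):  # oxygen group
            if deg >= 2:
                hyb = "sp3"
            elif deg == 1:
                hyb = "sp2"  # carbonyl-like terminal
        out.append(hyb)
    return out


def _pi_subsystems(mol: Molecule, neighbors: list, hyb: list):
    """sp2/sp atoms of C/N/O/S with at least one sp2/sp neighbor, grouped."""
    unsat = {
        a
        for a in range(mol.n_atoms)
        if hyb[a] in ("sp2", "sp") and int(mol.atomic_numbers[a]) in (5, 6, 7, 8, 16)
    }
    pi_atoms = sorted(
        a for a in unsat if any(b in unsat for b in neighbors[a])
    )
    g = nx.Graph()
    g.add_nodes_from(pi_atoms)
    for a in pi_atoms:
        for b in neighbors[a]:
            if b in pi_atoms:
                g.add_edge(a, b)
    systems = [sorted(c) for c in nx.connected_components(g)]
    return pi_atoms, sorted(systems)


def _pi_electrons(z: int, degree: int, topo_charge: float) -> float:
    """Hueckel pi-electron bookkeeping per center.

    sp2/sp carbon contributes 1; pyrrole-type N (three sigma neighbors) 2,
    pyridine-type N 1; divalent O (furan-type) 2, carbonyl-type O 1; S as O.
    Charged centers are adjusted by the rounded topology charge.
    """
    if z in (5, 6):
        base = 1.0
    elif z in (7, 15):
        base = 2.0 if degree == 3 else 1.0
    elif z in (8, 16):
        base = 2.0 if degree == 2 else 1.0
    else:
        base = 0.0
    return max(base - round(topo_charge), 0.0)


def huckel_bond_orders(
    topo: Topology,
    mol: Molecule,
    table: ParameterTable,
    charges: np.ndarray,
) -> dict:
    """One Hueckel pass over every conjugated subsystem.

    Returns {(i, j): pi bond order} for bonded pi pairs.  The Hamiltonian is
    H_ii = hueckel_alpha_i - k_q * q_i and H_ij = mean of the two elements'
    hueckel_beta for bonded pi pairs; levels are filled aufbau with two
    electrons each (a singly occupied level absorbs an odd count, with a
    warning).  Occupation conserves the pi-electron count exactly.
    """
    zs = mol.atomic_numbers
    k_q = table.globals.k_q
    bond_set = {(b.i, b.j) for b in topo.bonds}
    orders: dict = {}
    for system in topo.pi_systems:
        idx = {a: t for t, a in enumerate(system)}
        m = len(system)
        h = np.zeros((m, m))
        for a in system:
            h[idx[a], idx[a]] = table[int(zs[a])].hueckel_alpha - k_q * charges[a]
        nel = 0.0
        for a in system:
            nel += _pi_electrons(
                int(zs[a]), len(topo.neighbors[a]), float(charges[a])
            )
            for b in topo.neighbors[a]:
                if b in idx and (min(a, b), max(a, b)) in bond_set:
                    beta = 0.5 * (
                        table[int(zs[a])].hueckel_beta + table[int(zs[b])].hueckel_beta
                    )
                    h[idx[a], idx[b]] = beta
        nel_int = int(round(nel))
        evals, vecs = np.linalg.eigh(h)
        occ = np.zeros(m)
        remaining = nel_int
        for lv in range(m):
            if remaining <= 0:
                break
            take = min(2, remaining)
            occ[lv] = take
            remaining -= take
        if nel_int % 2 == 1:
            warnings.warn(
                f"odd pi-electron count ({nel_int}) in subsystem {system}; "
                "one singly occupied level",
                stacklevel=2,
            )
        dm = (vecs * occ[None, :]) @ vecs.T  # density matrix
        for a in system:
            for b in topo.neighbors[a]:
                if b > a and b in idx and (a, b) in bond_set:
                    orders[(a, b)] = float(dm[idx[a], idx[b]])
    return orders


def perceive_topology(
    mol: Molecule, table: ParameterTable | None = None
) -> Topology:
    """Full topology setup: the only place bonding information is created."""
    from .charges import solve_eeq  # local import: charges needs Topology

    table = table or default_table()
    n = mol.n_atoms
    pairs = detect_bonds(mol, table)
    neighbors = _neighbor_lists(n, pairs)
    angles = _enumerate_angles(neighbors)
    torsions = _enumerate_torsions(pairs, neighbors)
    rings = _find_rings(n, pairs)
    hyb = _hybridization(mol, neighbors)
    if pairs:
        rows = [p[0] for p in pairs] + [p[1] for p in pairs]
        cols = [p[1] for p in pairs] + [p[0] for p in pairs]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, fragments = connected_components(adj, directed=False)
    else:
        fragments = np.arange(n)
    pi_atoms, pi_systems = _pi_subsystems(mol, neighbors, hyb)
    cn, _ = coordination_numbers_with_derivs(mol.coords, mol.atomic_numbers, table)

    zs = mol.atomic_numbers
    bonds = [
        Bond(i, j, table.r0_bond(int(zs[i]), int(zs[j]), 1.0), 1.0)
        for i, j in pairs
    ]
    topo = Topology(
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        rings=rings,
        hybridization=hyb,
        fragments=fragments,
        pi_atoms=pi_atoms,
        pi_systems=pi_systems,
        cn=cn,
        topo_charges=np.zeros(n),
        neighbors=neighbors,
    )

    # fixed-point loop: bond orders -> r0 -> topology charges -> Hueckel
    # diagonal -> bond orders, until the orders stop changing
    prev = {(b.i, b.j): 0.0 for b in topo.bonds}
    for _ in range(50):
        topo.topo_charges = solve_eeq(mol, topo, table, mode="topology").q
        if not topo.pi_atoms:
            break
        orders = huckel_bond_orders(topo, mol, table, topo.topo_charges)
        delta = 0.0
        for b in topo.bonds:
            p = orders.get((b.i, b.j), 0.0)
            delta = max(delta, abs(p - prev.get((b.i, b.j), 0.0)))
            prev[(b.i, b.j)] = p
            b.bond_order = 1.0 + p
            b.r0 = table.r0_bond(int(zs[b.i]), int(zs[b.j]), b.bond_order)
        if delta < 1e-6:
            break
    else:
        warnings.warn(
            "Hueckel charge coupling did not converge in 50 iterations; "
            "using the last iterate",
            stacklevel=2,
        )
    return topo
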