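"""Electronegativity-equilibration (EEQ) atomic charges.

Two charge sets are produced.  The *geometry* set minimizes

    E(q) = sum_i (chi_i^eff q_i + 1/2 eta_i q_i^2) + sum_{i<j} q_i q_j A_ij

subject to sum_i q_i = Q_total, with the damped Coulomb kernel
A_ij = erf(r_ij/gamma_ij)/r_ij, gamma_ij = sqrt(gamma_i^2 + gamma_j^2),
and chi_i^eff = chi_i + c_cn,i * sqrt(CN_i).  The constrained minimum is a
single symmetric (N+1) x (N+1) linear solve (Lagrange multiplier).

The *topology* set replaces r_ij by distances along the bond graph (sum of
reference bond lengths on the shortest path, zero interaction beyond six
bonds) and uses integer neighbor counts in chi^eff, so it is strictly
invariant under any coordinate change that preserves the bond graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, shortest_path
from scipy.special import erf

from .constants import BOHR_PER_ANGSTROM
from .errors import IllConditionedError
from .io import Molecule
from .params import ParameterTable, default_table

SQRT_PI = np.sqrt(np.pi)


@dataclass
class ChargeSet:
    q: np.ndarray
    mode: str
    total: float
    energy: float


def coulomb_kernel(r: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """erf(r/gamma)/r, with its finite r -> 0 limit 2/(gamma sqrt(pi))."""
    r = np.asarray(r, float)
    small = r < 1e-10
    rs = np.where(small, 1.0, r)
    return np.where(small, 2.0 / (gamma * SQRT_PI), erf(rs / gamma) / rs)


def coulomb_kernel_deriv(r: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """d/dr of the damped kernel (0 at r = 0 by symmetry)."""
    r = np.asarray(r, float)
    small = r < 1e-10
    rs = np.where(small, 1.0, r)
    x = rs / gamma
    d = 2.0 * np.exp(-(x**2)) / (SQRT_PI * gamma * rs) - erf(x) / rs**2
    return np.where(small, 0.0, d)


def _gamma_matrix(zs, table: ParameterTable) -> np.ndarray:
    g = np.array([table[int(z)].gamma_q for z in zs])
    return np.sqrt(g[:, None] ** 2 + g[None, :] ** 2)


def chi_effective(zs, cn: np.ndarray, table: ParameterTable) -> np.ndarray:
    chi = np.array([table[int(z)].chi for z in zs])
    ccn = np.array([table[int(z)].c_cn for z in zs])
    return chi + ccn * np.sqrt(np.maximum(cn, 0.0) + 1e-30)


def topology_distances(mol: Molecule, topo, table: ParameterTable) -> np.ndarray:
    """Graph-derived distances in Bohr; inf where the bond path exceeds 6."""
    n = mol.n_atoms
    if not topo.bonds:
        return np.full((n, n), np.inf)
    rows = [b.i for b in topo.bonds] + [b.j for b in topo.bonds]
    cols = [b.j for b in topo.bonds] + [b.i for b in topo.bonds]
    w = [b.r0 * BOHR_PER_ANGSTROM for b in topo.bonds] * 2
    graph = csr_matrix((w, (rows, cols)), shape=(n, n))
    dist = dijkstra(graph, directed=False)
    hops = shortest_path(graph, directed=False, unweighted=True)
    dist[hops > 6] = np.inf
    return dist


def eeq_system(
    mol: Molecule,
    topo,
    table: ParameterTable,
    mode: str = "geometry",
    coords_bohr: np.ndarray | None = None,
):
    """Assemble (A, chi_eff, eta) for the requested mode."""
    zs = mol.atomic_numbers
    n = mol.n_atoms
    eta = np.array([table[int(z)].eta for z in zs])
    gamma = _gamma_matrix(zs, table)
    if mode == "geometry":
        xyz = coords_bohr if coords_bohr is not None else mol.coords_bohr
        d = xyz[:, None, :] - xyz[None, :, :]
        r = np.sqrt((d**2).sum(-1))
        from .topology import coordination_numbers_with_derivs

        cn, _ = coordination_numbers_with_derivs(
            xyz / BOHR_PER_ANGSTROM, zs, table
        )
    elif mode == "topology":
        r = topology_distances(mol, topo, table)
        cn = np.array([float(len(topo.neighbors[i])) for i in range(n)])
    else:
        raise ValueError(f"unknown EEQ mode {mode!r}")
    finite = np.isfinite(r)
    a = np.zeros((n, n))
    a[finite] = coulomb_kernel(r[finite], gamma[finite])
    np.fill_diagonal(a, 0.0)
    chi = chi_effective(zs, cn, table)
    return a, chi, eta


def _solve_bordered(a, chi, eta, total):
    n = len(chi)
    m = np.zeros((n + 1, n + 1))
    m[:n, :n] = a
    m[np.arange(n), np.arange(n)] = eta
    m[:n, n] = 1.0
    m[n, :n] = 1.0
    rhs = np.concatenate([-chi, [float(total)]])
    try:
        factor = lu_factor(m)
        sol = lu_solve(factor, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise IllConditionedError(np.inf) from exc
    if not np.all(np.isfinite(sol)):
        raise IllConditionedError(float(np.linalg.cond(m)))
    cond = np.linalg.cond(m)
    if cond > 1e12:
        raise IllConditionedError(float(cond))
    return sol[:n], sol[n], factor


def eeq_energy(q, a, chi, eta) -> float:
    return float(chi @ q + 0.5 * q @ (eta * q) + 0.5 * q @ (a @ q))


def solve_eeq(
    mol: Molecule,
    topo,
    table: ParameterTable | None = None,
    mode: str = "geometry",
    coords_bohr: np.ndarray | None = None,
) -> ChargeSet:
    """Constrained EEQ minimization as one symmetric linear solve."""
    table = table or default_table()
    a, chi, eta = eeq_system(mol, topo, table, mode, coords_bohr)
    q, _, _ = _solve_bordered(a, chi, eta, mol.total_charge)
    return ChargeSet(
        q=q,
        mode=mode,
        total=float(mol.total_charge),
        energy=eeq_energy(q, a, chi, eta),
    )
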