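"""Total-energy assembly, geometry optimization, dynamics, frequencies.

The total energy is the sum of the covalent part (bond, bend, torsion,
bonded repulsion, three-body correction) and the non-covalent part (EEQ
electrostatics, dispersion, HB/XB corrections, non-bonded repulsion); the
partition is exact and asserted to 1e-12.

The optimizer is a quasi-Newton (BFGS-updated) trust-radius method in
Cartesian coordinates.  Its initial Hessian is assembled *fragment-blocked*:
second derivatives are computed per covalent block (breadth-first split
above 300 atoms) and inter-block coupling is ignored, which is cheap and
asymptotically equivalent to the dense oracle for reaching the same
minimum.  A dense initial Hessian is available as the test oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AU_TIME_PER_FS,
    ELECTRON_MASS_PER_AMU,
    KB_HARTREE_PER_K,
    WAVENUMBER_PER_SQRT_AU,
)
from .energy_cov import CovalentTerms, assemble_covalent_terms, covalent_energy
from .energy_nci import (
    build_pair_list,
    dispersion_energy,
    electrostatic_energy,
    enumerate_hb_terms,
    hbond_xbond_energy,
    nci_repulsion,
)
from .errors import TrajectoryError
from .io import Molecule
from .params import ParameterTable, default_table
from .topology import Topology, perceive_topology

TERM_NAMES = (
    "e_bond",
    "e_bend",
    "e_tors",
    "e_rep_bond",
    "e_abc",
    "e_ies",
    "e_disp",
    "e_hb",
    "e_xb",
    "e_rep_nci",
)


@dataclass
class EnergyBreakdown:
    e_bond: float = 0.0
    e_bend: float = 0.0
    e_tors: float = 0.0
    e_rep_bond: float = 0.0
    e_abc: float = 0.0
    e_ies: float = 0.0
    e_disp: float = 0.0
    e_hb: float = 0.0
    e_xb: float = 0.0
    e_rep_nci: float = 0.0
    e_total: float = 0.0

    @property
    def e_cov(self) -> float:
        return self.e_bond + self.e_bend + self.e_tors + self.e_rep_bond + self.e_abc

    @property
    def e_nci(self) -> float:
        return self.e_ies + self.e_disp + self.e_hb + self.e_xb + self.e_rep_nci


@dataclass
class OptResult:
    final: Molecule
    cycles: int
    converged: bool
    energy_trace: list
    grad_norm: float


@dataclass
class Frame:
    step: int
    coords_bohr: np.ndarray
    velocities: np.ndarray
    e_pot: float
    e_kin: float
    temperature: float


@dataclass
class Trajectory:
    atomic_numbers: np.ndarray
    frames: list
    dt_fs: float
    thermostat: str
    seed: int | None = None


class ForceField:
    """Frozen-topology potential for one molecule.

    All term lists (bond parameters, angle/torsion tables, non-bonded pair
    list, HB/XB candidate triples, topology charges, dispersion
    coefficients) are assembled once at construction; subsequent energy and
    gradient evaluations only depend on the coordinates passed in.
    """

    def __init__(
        self,
        mol: Molecule,
        table: ParameterTable | None = None,
        topo: Topology | None = None,
    ):
        self.mol = mol
        self.table = table or default_table()
        self.topo = topo if topo is not None else perceive_topology(mol, self.table)
        self.cov: CovalentTerms = assemble_covalent_terms(mol, self.topo, self.table)
        self.pairs = build_pair_list(mol, self.topo, self.table)
        self.hb_terms, self.xb_terms = enumerate_hb_terms(mol, self.topo, self.table)
        self.q_topo = self.topo.topo_charges
        self.q_geom_last: np.ndarray | None = None
        self.pair_evaluations = 0

    # -- evaluation ---------------------------------------------------------

    def energy_gradient(self, xyz: np.ndarray):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        n = xyz.shape[0]
        terms_cov, g_cov = covalent_energy(xyz, self.cov)
        if n > 1:
            e_ies, g_ies, q_geom, _ = electrostatic_energy(
                self.mol, self.topo, self.table, xyz, self.q_topo
            )
            self.q_geom_last = q_geom
        else:
            e_ies, g_ies = 0.0, np.zeros((1, 3))
            self.q_geom_last = np.array([float(self.mol.total_charge)])
        e_disp, g_disp = dispersion_energy(
            xyz, self.pairs, self.mol.atomic_numbers, self.q_topo, self.table
        )
        e_rep_nci, g_rep_nci = nci_repulsion(
            xyz, self.pairs, self.mol.atomic_numbers, self.table
        )
        e_hb, e_xb, g_hbxb = hbond_xbond_energy(
            xyz, self.hb_terms, self.xb_terms, self.table
        )
        self.pair_evaluations += n * (n - 1) // 2 + 2 * len(self.pairs) + len(
            self.hb_terms
        ) + len(self.xb_terms)
        bd = EnergyBreakdown(
            **terms_cov,
            e_ies=e_ies,
            e_disp=e_disp,
            e_hb=e_hb,
            e_xb=e_xb,
            e_rep_nci=e_rep_nci,
        )
        bd.e_total = (
            bd.e_bond
            + bd.e_bend
            + bd.e_tors
            + bd.e_rep_bond
            + bd.e_abc
            + bd.e_ies
            + bd.e_disp
            + bd.e_hb
            + bd.e_xb
            + bd.e_rep_nci
        )
        grad = g_cov + g_ies + g_disp + g_rep_nci + g_hbxb
        return bd, grad

    def energy(self, xyz: np.ndarray) -> float:
        return self.energy_gradient(xyz)[0].e_total

    def gradient(self, xyz: np.ndarray) -> np.ndarray:
        return self.energy_gradient(xyz)[1]

    # -- Hessians -----------------------------------------------------------

    def _blocks(self, max_block: int = 300) -> list:
        frag = self.topo.fragments
        blocks = []
        for f in sorted(set(frag.tolist())):
            atoms = [i for i in range(self.mol.n_atoms) if frag[i] == f]
            for s in range(0, len(atoms), max_block):
                blocks.append(atoms[s : s + max_block])
        return blocks

    def numerical_hessian(
        self, xyz: np.ndarray, fragmented: bool = False, step: float = 0.005
    ) -> np.ndarray:
        """Central-difference Hessian of the analytic gradient (a.u.).

        fragmented=True fills only the per-block diagonal blocks (the
        fragmented-Hessian scheme); False is the dense oracle.
        """
        xyz = np.asarray(xyz, float).reshape(-1, 3)
        n = xyz.shape[0]
        h = np.zeros((3 * n, 3 * n))
        cols = (
            [(a, d) for blk in self._blocks() for a in blk for d in range(3)]
            if fragmented
            else [(a, d) for a in range(n) for d in range(3)]
        )
        block_of = {}
        if fragmented:
            for bi, blk in enumerate(self._blocks()):
                for a in blk:
                    block_of[a] = bi
        for a, d in cols:
            x1 = xyz.copy()
            x1[a, d] += step
            gp = self.gradient(x1)
            x1[a, d] -= 2 * step
            gm = self.gradient(x1)
            col = ((gp - gm) / (2 * step)).ravel()
            if fragmented:
                mask = np.zeros(3 * n, bool)
                for b in range(n):
                    if block_of.get(b) == block_of.get(a):
                        mask[3 * b : 3 * b + 3] = True
                col = np.where(mask, col, 0.0)
            h[:, 3 * a + d] = col
        return 0.5 * (h + h.T)


def total_energy_gradient(
    mol: Molecule,
    topo: Topology | None = None,
    table: ParameterTable | None = None,
):
    """One-shot breakdown + gradient (topology perceived if not given)."""
    ff = ForceField(mol, table, topo)
    return ff.energy_gradient(mol.coords_bohr)


# ---------------------------------------------------------------------------
# geometry optimization
# ---------------------------------------------------------------------------


def optimize_geometry(
    mol: Molecule,
    topo: Topology | None = None,
    table: ParameterTable | None = None,
    *,
    max_cycles: int = 500,
    e_tol: float = 5e-6,
    g_tol: float = 1e-3,
    hessian: str = "fragmented",
    trust: float = 0.3,
    ff: ForceField | None = None,
) -> OptResult:
    """Quasi-Newton minimization with a fragment-blocked initial Hessian.

    Steps are trust-radius-regularized Newton directions on a BFGS-updated
    Hessian; a backtracking line search guarantees that accepted steps never
    increase the energy, so the energy trace is monotone non-increasing.
    """
    if ff is None:
        ff = ForceField(mol, table, topo)
    x = mol.coords_bohr.ravel().copy()
    n3 = x.size
    bd, g = ff.energy_gradient(x)
    e = bd.e_total
    g = g.ravel()
    trace = [e]
    h = ff.numerical_hessian(x, fragmented=(hessian == "fragmented"))
    # regularize: translation/rotation null space and weak modes
    converged = np.linalg.norm(g) < g_tol
    cycles = 0
    tr = trust
    while not converged and cycles < max_cycles:
        cycles += 1
        # spectral shift to make the step well-defined inside the trust region
        evals = np.linalg.eigvalsh(h)
        lam = max(0.0, -float(evals[0])) + 1e-4
        step = np.linalg.solve(h + lam * np.eye(n3), -g)
        norm = np.linalg.norm(step)
        if norm > tr:
            step *= tr / norm
        # backtracking line search on the energy
        alpha = 1.0
        accepted = False
        for _ in range(12):
            x_new = x + alpha * step
            bd_new, g_new = ff.energy_gradient(x_new)
            if bd_new.e_total <= e + 1e-14:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            tr *= 0.25
            if tr < 1e-8:
                break
            continue
        s = x_new - x
        y = g_new.ravel() - g
        sy = float(s @ y)
        if sy > 1e-12:
            hs = h @ s
            h = h + np.outer(y, y) / sy - np.outer(hs, hs) / float(s @ hs)
        de = e - bd_new.e_total
        x, e, g = x_new, bd_new.e_total, g_new.ravel()
        trace.append(e)
        if alpha == 1.0 and np.linalg.norm(step) < 0.8 * tr:
            tr = min(tr * 1.4, 1.0)
        gnorm = np.linalg.norm(g)
        if gnorm < g_tol and de < e_tol:
            converged = True
    final = mol.with_coords_bohr(x.reshape(-1, 3))
    return OptResult(
        final=final,
        cycles=cycles,
        converged=bool(converged),
        energy_trace=trace,
        grad_norm=float(np.linalg.norm(g)),
    )


# ---------------------------------------------------------------------------
# molecular dynamics
# ---------------------------------------------------------------------------


def _is_linear(xyz: np.ndarray, tol: float = 1e-6) -> bool:
    if xyz.shape[0] < 3:
        return True
    c = xyz - xyz.mean(0)
    _, s, _ = np.linalg.svd(c)
    return bool(s[1] < tol * max(s[0], 1.0))


def _kinetic_temperature(v: np.ndarray, masses: np.ndarray, ndof: int):
    ekin = 0.5 * float((masses[:, None] * v**2).sum())
    t = 2.0 * ekin / (ndof * KB_HARTREE_PER_K) if ndof > 0 else 0.0
    return ekin, t


def run_md(
    mol: Molecule,
    topo: Topology | None = None,
    table: ParameterTable | None = None,
    *,
    dt_fs: float = 0.5,
    n_steps: int = 1000,
    t_kelvin: float = 298.0,
    thermostat: str = "none",
    seed: int = 0,
    stride: int = 10,
    tau_fs: float = 100.0,
    rescale_every: int = 50,
    ff: ForceField | None = None,
) -> Trajectory:
    """Velocity-Verlet dynamics in atomic units.

    Initial velocities are Maxwell-Boltzmann at ``t_kelvin`` from a seeded
    generator (zero exactly when t_kelvin == 0); center-of-mass momentum is
    removed.  Thermostats: none (NVE), berendsen (tau = ``tau_fs``), or
    velocity rescale every ``rescale_every`` steps.
    """
    if dt_fs > 2.0:
        raise ValueError("time step above 2 fs is not supported")
    if ff is None:
        ff = ForceField(mol, table, topo)
    masses = mol.masses_amu * ELECTRON_MASS_PER_AMU
    n = mol.n_atoms
    x = mol.coords_bohr.copy()
    ndof = max(3 * n - (5 if _is_linear(x) else 6), 1)
    rng = np.random.default_rng(seed)
    if t_kelvin > 0:
        sigma = np.sqrt(KB_HARTREE_PER_K * t_kelvin / masses)
        v = rng.standard_normal((n, 3)) * sigma[:, None]
        p = (masses[:, None] * v).sum(0)
        v -= p / masses.sum()
        ekin, t_now = _kinetic_temperature(v, masses, ndof)
        if t_now > 0:
            v *= math.sqrt(t_kelvin / t_now)
    else:
        v = np.zeros((n, 3))
    dt = dt_fs * AU_TIME_PER_FS

    bd, g = ff.energy_gradient(x)
    acc = -g / masses[:, None]
    frames = []

    def record(step):
        ekin, t_now = _kinetic_temperature(v, masses, ndof)
        frames.append(
            Frame(step, x.copy(), v.copy(), bd.e_total, ekin, t_now)
        )

    record(0)
    if not np.isfinite(bd.e_total) or abs(bd.e_total) > 1e4:
        raise TrajectoryError(
            f"initial configuration diverged (E = {bd.e_total!r})",
            last_frame=frames[-1],
        )
    for step in range(1, n_steps + 1):
        v_half = v + 0.5 * dt * acc
        x = x + dt * v_half
        bd, g = ff.energy_gradient(x)
        if not np.isfinite(bd.e_total) or abs(bd.e_total) > 1e4:
            raise TrajectoryError(
                f"energy diverged at step {step} (E = {bd.e_total!r})",
                last_frame=frames[-1] if frames else None,
            )
        acc = -g / masses[:, None]
        v = v_half + 0.5 * dt * acc
        if thermostat == "berendsen" and t_kelvin > 0:
            _, t_now = _kinetic_temperature(v, masses, ndof)
            if t_now > 0:
                lam = math.sqrt(
                    1.0 + (dt_fs / tau_fs) * (t_kelvin / t_now - 1.0)
                )
                v *= lam
        elif thermostat == "rescale" and t_kelvin > 0 and step % rescale_every == 0:
            _, t_now = _kinetic_temperature(v, masses, ndof)
            if t_now > 0:
                v *= math.sqrt(t_kelvin / t_now)
        if step % stride == 0 or step == n_steps:
            record(step)
    return Trajectory(
        atomic_numbers=mol.atomic_numbers.copy(),
        frames=frames,
        dt_fs=dt_fs,
        thermostat=thermostat,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# harmonic frequencies
# ---------------------------------------------------------------------------


def harmonic_frequencies(
    mol: Molecule,
    topo: Topology | None = None,
    table: ParameterTable | None = None,
    *,
    step: float = 0.005,
    ff: ForceField | None = None,
) -> np.ndarray:
    """Wavenumbers (cm^-1) from the mass-weighted numerical Hessian.

    Translations/rotations are projected out (their modes appear near zero);
    imaginary modes are reported as negative numbers.  The full 3N spectrum
    is returned so mode counting stays transparent.
    """
    if ff is None:
        ff = ForceField(mol, table, topo)
    xyz = mol.coords_bohr
    g = ff.gradient(xyz)
    if np.abs(g).max() > 1e-4:
        warnings.warn(
            "harmonic analysis off-minimum (max |g| = "
            f"{np.abs(g).max():.2e} Hartree/Bohr)",
            stacklevel=2,
        )
    n = mol.n_atoms
    h = ff.numerical_hessian(xyz, fragmented=False, step=step)
    masses = mol.masses_amu * ELECTRON_MASS_PER_AMU
    msqrt = np.repeat(np.sqrt(masses), 3)
    hw = h / np.outer(msqrt, msqrt)

    # projector onto the complement of rigid translations/rotations
    c = xyz - (masses[:, None] * xyz).sum(0) / masses.sum()
    basis = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = np.sqrt(masses)
        basis.append(t.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        r = np.cross(c, axis) * np.sqrt(masses)[:, None]
        if np.linalg.norm(r) > 1e-8:
            basis.append(r.ravel())
    b = np.array(basis).T
    qmat, _ = np.linalg.qr(b)
    proj = np.eye(3 * n) - qmat @ qmat.T
    hw = proj @ hw @ proj
    evals = np.linalg.eigvalsh(hw)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * WAVENUMBER_PER_SQRT_AU
    return np.sort(freqs)
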