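"""Per-element parameter registry and fitting harness.

Every element from hydrogen to radon carries exactly 18 scalar parameters
(asserted in the schema) that drive all energy terms; everything that refers
to a *pair* of elements is produced by combination rules over these values
plus a small set of named global scalars.  No element-pair-specific
parameters exist anywhere.

Defaults are derived from tabulated covalent radii, electronegativities and
free-atom polarizabilities (see ``_element_data``).  A curated subset
(H, C, N, O, F, Na, P, S, Cl) is marked fitted; all other elements carry the
rule-derived defaults and are flagged ``unfitted`` in the table metadata.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields

import numpy as np

from . import _element_data as edata
from .constants import BOHR_PER_ANGSTROM
from .errors import FitDivergedError, UnsupportedElementError

MAX_Z = edata.MAX_Z

#: the 18 per-element parameter names, in canonical order
ELEMENT_PARAM_NAMES = (
    "chi",          # electronegativity (a.u.)
    "eta",          # chemical hardness (a.u.)
    "gamma_q",      # charge-distribution width (Bohr)
    "c_cn",         # CN dependence of chi (a.u.)
    "r_cov",        # covalent radius (Angstrom)
    "z_rep",        # effective repulsion charge
    "alpha_rep",    # repulsion exponent (Bohr^-3/2)
    "k_bond",       # base bond well depth (Hartree)
    "alpha_bond",   # bond Gaussian width (Bohr^-2)
    "k_bend",       # base angle force constant (Hartree)
    "k_tors",       # base torsion force constant (Hartree)
    "c6_ref",       # reference C6 dispersion coefficient (a.u.)
    "alpha_pol",    # static polarizability (a.u.)
    "hb_acid",      # hydrogen-bond donor strength
    "hb_base",      # hydrogen-bond acceptor strength
    "xb_str",       # halogen-bond donor strength
    "hueckel_alpha",  # Hueckel on-site energy (a.u.)
    "hueckel_beta",   # Hueckel resonance scale (a.u.)
)


@dataclass(frozen=True)
class ElementParams:
    chi: float
    eta: float
    gamma_q: float
    c_cn: float
    r_cov: float
    z_rep: float
    alpha_rep: float
    k_bond: float
    alpha_bond: float
    k_bend: float
    k_tors: float
    c6_ref: float
    alpha_pol: float
    hb_acid: float
    hb_base: float
    xb_str: float
    hueckel_alpha: float
    hueckel_beta: float


assert tuple(f.name for f in fields(ElementParams)) == ELEMENT_PARAM_NAMES
assert len(ELEMENT_PARAM_NAMES) == 18


@dataclass
class GlobalParams:
    """Named global scalars shared by all elements.

    Signed values: ``c_en`` is negative (bonds between atoms of unequal
    electronegativity contract), and the Hueckel on-site/resonance energies
    stored per element are negative by the usual tight-binding convention.
    """

    k_cn: float = 16.0        # CN counting-function steepness
    f_bond: float = 1.25      # bond-detection scale on covalent radii
    s6: float = 1.0           # dipole-dipole dispersion scale
    s8: float = 1.5           # dipole-quadrupole dispersion scale
    a1: float = 0.45          # BJ damping radius scale
    a2: float = 4.0           # BJ damping radius offset (Bohr)
    k_hb: float = 0.0025      # hydrogen-bond prefactor (Hartree)
    k_xb: float = 0.0015      # halogen-bond prefactor (Hartree)
    k3: float = 0.02          # three-body bond-correction scale
    k_q: float = 0.2          # Hueckel diagonal charge coupling (a.u./e)
    c_en: float = -0.04       # r0 electronegativity correction (Angstrom, signed)
    c_bo: float = 0.08        # r0 bond-order contraction (Angstrom)
    p_bo: float = 0.8         # bond-order exponent of the well depth
    k_damp: float = 8.0       # bend/torsion damping steepness
    s_damp: float = 1.5       # bend/torsion damping onset (units of r0)
    k_tors_pi: float = 0.02   # pi-torsion barrier scale (Hartree)
    s_rep_nci: float = 0.5    # non-bonded repulsion scale
    c_rep_nci: float = 0.6    # non-bonded repulsion exponent scale
    scale_14: float = 0.5     # 1,4 NCI pair scaling
    cut_disp: float = 40.0    # dispersion cutoff (Bohr)
    cut_rep: float = 25.0     # non-bonded repulsion cutoff (Bohr)
    cut_hb: float = 15.0      # HB/XB cutoff (Bohr)
    k_gq: float = 2.0         # HB charge-factor exponent (1/e)
    hb_rscale: float = 2.0    # HB well position scale on radii sums
    hb_width: float = 0.30    # HB well width (Bohr^-2)
    xb_rscale: float = 2.2    # XB well position scale
    xb_width: float = 0.25    # XB well width (Bohr^-2)


def _default_element(z: int) -> ElementParams:
    i = z - 1
    en = edata.EN_PAULING[i]
    r_cov = edata.R_COV_ANGSTROM[i]
    r_cov_bohr = r_cov * BOHR_PER_ANGSTROM
    alpha = edata.ALPHA_AU[i]
    nval = min(edata.N_VALENCE[i], 8)

    gamma_q = max(1.2, 1.2 * r_cov_bohr)
    # hardness: Gaussian self-interaction floor plus a chemical offset,
    # guaranteeing a positive-definite EEQ matrix
    eta = math.sqrt(2.0 / math.pi) / gamma_q + 0.2 + 0.02 * en
    chi = 0.15 * en
    c6 = edata.C6_CURATED.get(z)
    if c6 is None:
        # London-type estimate with an EN-scaled effective excitation energy
        c6 = 0.75 * alpha * alpha * (0.15 + 0.08 * en)
    return ElementParams(
        chi=chi,
        eta=eta,
        gamma_q=gamma_q,
        c_cn=-0.01,
        r_cov=r_cov,
        z_rep=0.5 + 0.3 * nval,
        alpha_rep=1.5 / r_cov_bohr**0.75,
        k_bond=0.08 + 0.02 * nval,
        alpha_bond=0.9 / r_cov_bohr + 0.4,
        k_bend=0.06 + 0.01 * nval,
        k_tors=0.0003,
        c6_ref=c6,
        alpha_pol=alpha,
        hb_acid={7: 0.8, 8: 1.0, 9: 1.2, 16: 0.5, 17: 0.4}.get(z, 0.0),
        hb_base={7: 1.1, 8: 1.0, 9: 0.8, 16: 0.6, 17: 0.5}.get(z, 0.0),
        xb_str={17: 0.3, 35: 0.6, 53: 1.0}.get(z, 0.0),
        hueckel_alpha=-0.41 - 0.10 * (en - 2.55),
        hueckel_beta=-0.10,
    )


class ParameterTable:
    """Registry mapping Z -> :class:`ElementParams` plus global scalars."""

    def __init__(
        self,
        elements: dict[int, ElementParams] | None = None,
        globals_: GlobalParams | None = None,
        unfitted: set[int] | None = None,
        version: str = "1",
    ):
        if elements is None:
            elements = {z: _default_element(z) for z in range(1, MAX_Z + 1)}
        self.elements = elements
        self.globals = globals_ if globals_ is not None else GlobalParams()
        if unfitted is None:
            unfitted = set(range(1, MAX_Z + 1)) - edata.CURATED_Z
        self.unfitted = unfitted
        self.version = version

    # -- access ------------------------------------------------------------

    def get_element_params(self, z: int) -> ElementParams:
        if not isinstance(z, (int, np.integer)) or z < 1 or z > MAX_Z:
            raise UnsupportedElementError(int(z))
        return self.elements[int(z)]

    def __getitem__(self, z: int) -> ElementParams:
        return self.get_element_params(z)

    def copy(self) -> "ParameterTable":
        return ParameterTable(
            dict(self.elements),
            dataclasses.replace(self.globals),
            set(self.unfitted),
            self.version,
        )

    def with_element_value(self, z: int, name: str, value: float) -> "ParameterTable":
        new = self.copy()
        new.elements[z] = dataclasses.replace(new.elements[z], **{name: value})
        return new

    # -- combination rules ---------------------------------------------------
    # well depths and C6: geometric mean; radii and exponents: arithmetic mean

    def pair_r_cov(self, zi: int, zj: int) -> float:
        return self[zi].r_cov + self[zj].r_cov

    def pair_k_bond(self, zi: int, zj: int) -> float:
        return math.sqrt(self[zi].k_bond * self[zj].k_bond)

    def pair_alpha_bond(self, zi: int, zj: int) -> float:
        return 0.5 * (self[zi].alpha_bond + self[zj].alpha_bond)

    def pair_alpha_rep(self, zi: int, zj: int) -> float:
        return math.sqrt(self[zi].alpha_rep * self[zj].alpha_rep)

    def r0_bond(self, zi: int, zj: int, bond_order: float = 1.0) -> float:
        """Reference bond length in Angstrom from radii, EN and bond order."""
        g = self.globals
        den = abs(edata.EN_PAULING[zi - 1] - edata.EN_PAULING[zj - 1])
        return (
            self[zi].r_cov
            + self[zj].r_cov
            + g.c_en * den
            - g.c_bo * math.log(max(bond_order, 1e-8))
        )

    # -- serialization -------------------------------------------------------

    def dumps(self) -> str:
        lines = [f"# genff parameter table v{self.version}", "[globals]"]
        for f in fields(GlobalParams):
            lines.append(f"{f.name} = {getattr(self.globals, f.name)!r}")
        for z in sorted(self.elements):
            sym = edata.SYMBOLS[z - 1]
            fitted = "false" if z in self.unfitted else "true"
            lines.append(f"[element {z} {sym} fitted={fitted}]")
            p = self.elements[z]
            for name in ELEMENT_PARAM_NAMES:
                lines.append(f"{name} = {getattr(p, name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "ParameterTable":
        elements: dict[int, ElementParams] = {}
        unfitted: set[int] = set()
        gvals: dict[str, float] = {}
        version = "1"
        section = None
        current_z = None
        current: dict[str, float] = {}

        def flush():
            if current_z is not None:
                elements[current_z] = ElementParams(**current)

        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "parameter table v" in line:
                    version = line.rsplit("v", 1)[1].strip()
                continue
            if line.startswith("["):
                flush()
                current = {}
                current_z = None
                tag = line.strip("[]")
                if tag == "globals":
                    section = "globals"
                else:
                    section = "element"
                    parts = tag.split()
                    current_z = int(parts[1])
                    if "fitted=false" in parts[-1]:
                        unfitted.add(current_z)
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            value = float(val.strip())
            if section == "globals":
                gvals[key] = value
            else:
                current[key] = value
        flush()
        known = {f.name for f in fields(GlobalParams)}
        globals_ = GlobalParams(**{k: v for k, v in gvals.items() if k in known})
        return cls(elements, globals_, unfitted, version)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "ParameterTable":
        with open(path) as fh:
            return cls.loads(fh.read())


_DEFAULT_TABLE: ParameterTable | None = None


def default_table() -> ParameterTable:
    """The shipped parameterization (shared instance; treat as read-only)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ParameterTable()
    return _DEFAULT_TABLE


def get_element_params(z: int) -> ElementParams:
    """Parameters of element ``z`` from the shipped default table."""
    return default_table().get_element_params(z)


# ---------------------------------------------------------------------------
# fitting harness
# ---------------------------------------------------------------------------


@dataclass
class Target:
    """One reference observable for the least-squares fit.

    kind:
      - ``bond_length``: distance (Angstrom) between ``atoms=(i, j)`` after a
        geometry optimization of ``fixture``.
      - ``angle``: angle (degrees) at the middle atom of ``atoms=(i, j, k)``
        after optimization.
      - ``energy_gap``: E(coords_b) - E(fixture coords), Hartree, evaluated at
        fixed geometries (no optimization).
    """

    kind: str
    fixture: int
    atoms: tuple
    ref: float = 0.0
    coords_b: np.ndarray | None = None
    weight: float = 1.0


@dataclass
class FitResult:
    table: ParameterTable
    initial_residual: float
    final_residual: float
    n_evaluations: int
    free: list = field(default_factory=list)


def _parse_free_name(name: str) -> tuple[str, str | int]:
    """``"k_bond:H"`` -> ("k_bond", 1); ``"global:c_en"`` -> ("global", "c_en")."""
    head, _, tail = name.partition(":")
    if head == "global":
        return ("global", tail)
    z = edata.ATOMIC_NUMBER.get(tail)
    if z is None:
        z = int(tail)
    if head not in ELEMENT_PARAM_NAMES:
        raise KeyError(f"unknown element parameter {head!r}")
    return (head, z)


def _apply_vector(table: ParameterTable, free: list, x: np.ndarray) -> ParameterTable:
    new = table.copy()
    for (name, which), val in zip(free, x):
        if name == "global":
            setattr(new.globals, which, float(val))
        else:
            new.elements[which] = dataclasses.replace(
                new.elements[which], **{name: float(val)}
            )
    return new


def evaluate_targets(
    table: ParameterTable, fixtures: list, targets: list[Target]
) -> np.ndarray:
    """Compute the observable value of every target with the given table."""
    from .engine import ForceField, optimize_geometry

    values = np.empty(len(targets))
    opt_cache: dict[int, np.ndarray] = {}
    for t_idx, t in enumerate(targets):
        mol = fixtures[t.fixture]
        if t.kind in ("bond_length", "angle"):
            if t.fixture not in opt_cache:
                res = optimize_geometry(mol, table=table, max_cycles=200)
                opt_cache[t.fixture] = res.final.coords_bohr
            xyz = opt_cache[t.fixture]
            if t.kind == "bond_length":
                i, j = t.atoms
                values[t_idx] = (
                    np.linalg.norm(xyz[i] - xyz[j]) / BOHR_PER_ANGSTROM
                )
            else:
                i, j, k = t.atoms
                u = xyz[i] - xyz[j]
                v = xyz[k] - xyz[j]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                values[t_idx] = math.degrees(math.acos(np.clip(c, -1.0, 1.0)))
        elif t.kind == "energy_gap":
            ff = ForceField(mol, table)
            ea = ff.energy(mol.coords_bohr)
            eb = ff.energy(np.asarray(t.coords_b, dtype=float))
            values[t_idx] = eb - ea
        else:
            raise ValueError(f"unknown target kind {t.kind!r}")
    return values


def generate_targets(
    table: ParameterTable, fixtures: list, specs: list[Target]
) -> list[Target]:
    """Fill in the reference values of ``specs`` using ``table`` itself."""
    vals = evaluate_targets(table, fixtures, specs)
    return [dataclasses.replace(t, ref=float(v)) for t, v in zip(specs, vals)]


def fit_parameters(
    table: ParameterTable,
    fixtures: list,
    targets: list[Target],
    free: list[str],
    xtol: float = 1e-10,
    max_nfev: int = 200,
) -> FitResult:
    """Damped least squares over the named free parameters.

    Accepted trust-region iterations never increase the residual (monotone by
    construction of the underlying Levenberg-Marquardt/TRF solver).
    """
    from scipy.optimize import least_squares

    parsed = [_parse_free_name(n) for n in free]
    refs = np.array([t.ref for t in targets], dtype=float)
    weights = np.array([t.weight for t in targets], dtype=float)
    nfev = [0]

    def residuals(x: np.ndarray) -> np.ndarray:
        nfev[0] += 1
        tab = _apply_vector(table, parsed, x)
        r = (evaluate_targets(tab, fixtures, targets) - refs) * weights
        if not np.all(np.isfinite(r)):
            raise FitDivergedError(
                "non-finite residual during fitting", x=np.array(x)
            )
        return r

    if not parsed:
        r0 = residuals(np.empty(0)) if targets else np.empty(0)
        res0 = float(np.sqrt(np.sum(r0**2)))
        return FitResult(table, res0, res0, nfev[0], [])

    x0 = np.array(
        [
            getattr(table.globals, w) if n == "global" else getattr(table.elements[w], n)
            for n, w in parsed
        ],
        dtype=float,
    )
    r_init = residuals(x0)
    initial = float(np.sqrt(np.sum(r_init**2)))
    sol = least_squares(
        residuals, x0, method="lm" if len(targets) >= len(x0) else "trf",
        xtol=xtol, max_nfev=max_nfev,
    )
    final = float(np.sqrt(np.sum(sol.fun**2)))
    if final <= initial:
        best = _apply_vector(table, parsed, sol.x)
    else:  # pragma: no cover - LM is monotone; keep the contract anyway
        best, final = table, initial
    return FitResult(best, initial, final, nfev[0], free)
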