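"""Molecular structure and trajectory I/O.

Supported structure formats: XYZ (primary; an optional ``charge=<int>``
token on the comment line carries the total molecular charge, since bare XYZ
has no charge field), a PDB subset (ATOM/HETATM records, element +
coordinates only; residue metadata is kept as opaque annotation), and
Turbomole ``coord`` blocks (Bohr).  Coordinates are stored in Angstrom on
the :class:`Molecule`; everything downstream of I/O works in atomic units
via :attr:`Molecule.coords_bohr`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from ._element_data import ATOMIC_NUMBER, MASSES_AMU, MAX_Z, SYMBOLS
from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from .errors import ParseError, TrajectoryError, UnsupportedElementError

MIN_CONTACT_ANGSTROM = 0.25


@dataclass
class Molecule:
    """Atomic numbers, Cartesian coordinates (Angstrom) and total charge."""

    atomic_numbers: np.ndarray
    coords: np.ndarray
    total_charge: int = 0
    title: str = ""
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.n_atoms < 1:
            raise ValueError("a Molecule needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        bad = (self.atomic_numbers < 1) | (self.atomic_numbers > MAX_Z)
        if np.any(bad):
            raise UnsupportedElementError(int(self.atomic_numbers[bad][0]))
        self._clash_guard()

    def _clash_guard(self):
        if self.n_atoms > 1:
            d = self.coords[:, None, :] - self.coords[None, :, :]
            r = np.sqrt((d**2).sum(-1))
            iu = np.triu_indices(self.n_atoms, k=1)
            rmin = r[iu].min()
            if rmin < MIN_CONTACT_ANGSTROM:
                warnings.warn(
                    f"atoms closer than {MIN_CONTACT_ANGSTROM} A "
                    f"(min contact {rmin:.3f} A)",
                    stacklevel=3,
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * BOHR_PER_ANGSTROM

    @property
    def symbols(self) -> list[str]:
        return [SYMBOLS[z - 1] for z in self.atomic_numbers]

    @property
    def masses_amu(self) -> np.ndarray:
        return np.array([MASSES_AMU[z - 1] for z in self.atomic_numbers])

    def with_coords_bohr(self, xyz: np.ndarray) -> "Molecule":
        return Molecule(
            self.atomic_numbers.copy(),
            np.asarray(xyz, float).reshape(-1, 3) * ANGSTROM_PER_BOHR,
            self.total_charge,
            self.title,
            list(self.annotations),
        )


def _symbol_to_z(sym: str, line: int | None = None) -> int:
    s = sym.strip().capitalize()
    z = ATOMIC_NUMBER.get(s)
    if z is None:
        # numeric atomic number is tolerated
        try:
            z = int(s)
        except ValueError:
            raise ParseError(f"unknown element symbol {sym!r}", line) from None
        if not 1 <= z <= MAX_Z:
            raise UnsupportedElementError(z)
    return z


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_xyz(text: str) -> Molecule:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input", 1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("first XYZ line must be the atom count", 1) from None
    comment = lines[1] if len(lines) > 1 else ""
    charge = 0
    for tok in comment.split():
        if tok.startswith("charge="):
            try:
                charge = int(tok.split("=", 1)[1])
            except ValueError:
                raise ParseError(f"malformed charge token {tok!r}", 2) from None
    zs, xyz = [], []
    for i in range(n):
        ln = 2 + i
        if ln >= len(lines) or not lines[ln].split():
            raise ParseError(
                f"XYZ header declares {n} atoms but only {i} found",
                min(ln, len(lines)),
            )
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError("expected '<symbol> x y z'", ln + 1)
        zs.append(_symbol_to_z(parts[0], ln + 1))
        try:
            xyz.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError("malformed coordinate triple", ln + 1) from None
    return Molecule(np.array(zs), np.array(xyz), charge, comment.strip())


def _parse_pdb(text: str) -> Molecule:
    zs, xyz, notes = [], [], []
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise ParseError("malformed PDB coordinates", ln) from None
        elem = line[76:78].strip()
        if not elem:
            # fallback: first alphabetic characters of the atom name
            name = line[12:16].strip()
            elem = "".join(c for c in name if c.isalpha())[:2]
            if elem[:1] in "HCNOSP" and elem.capitalize() not in ATOMIC_NUMBER:
                elem = elem[0]
        zs.append(_symbol_to_z(elem, ln))
        xyz.append([x, y, z])
        notes.append(line[12:27])  # atom name / residue / chain / resseq
    if not zs:
        raise ParseError("no ATOM/HETATM records found")
    return Molecule(np.array(zs), np.array(xyz), 0, "", notes)


def _parse_coord(text: str) -> Molecule:
    lines = text.splitlines()
    inside = False
    zs, xyz = [], []
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if s.startswith("$coord"):
            inside = True
            continue
        if s.startswith("$"):
            inside = False
            continue
        if not inside or not s:
            continue
        parts = s.split()
        if len(parts) < 4:
            raise ParseError("expected 'x y z symbol'", ln)
        try:
            vec = [float(p) for p in parts[:3]]
        except ValueError:
            raise ParseError("malformed coordinate triple", ln) from None
        zs.append(_symbol_to_z(parts[3], ln))
        xyz.append(vec)
    if not zs:
        raise ParseError("no $coord block found")
    return Molecule(np.array(zs), np.array(xyz) * ANGSTROM_PER_BOHR, 0, "")


def _sniff_format(source: str, text: str) -> str:
    if source:
        ext = os.path.splitext(source)[1].lower()
        if ext == ".xyz":
            return "xyz"
        if ext in (".pdb", ".ent"):
            return "pdb"
        if os.path.basename(source) == "coord" or ext == ".coord":
            return "coord"
    if "$coord" in text:
        return "coord"
    for line in text.splitlines():
        if line[:6].strip() in ("ATOM", "HETATM"):
            return "pdb"
        break
    return "xyz"


def read_structure(source, fmt: str = "auto", charge: int | None = None) -> Molecule:
    """Read a structure from a path or from literal text."""
    path = ""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and (
        "\n" not in str(source) and os.path.exists(source)
    ):
        path = str(source)
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    if fmt == "auto":
        fmt = _sniff_format(path, text)
    if fmt == "xyz":
        mol = _parse_xyz(text)
    elif fmt == "pdb":
        mol = _parse_pdb(text)
    elif fmt == "coord":
        mol = _parse_coord(text)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if charge is not None:
        mol.total_charge = int(charge)
    return mol


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _xyz_body(mol: Molecule, comment: str) -> str:
    out = [str(mol.n_atoms), comment]
    for sym, (x, y, z) in zip(mol.symbols, mol.coords):
        out.append(f"{sym:<2s} {x:20.12f} {y:20.12f} {z:20.12f}")
    return "\n".join(out) + "\n"


def write_structure(mol: Molecule, fmt: str = "xyz", path=None) -> str:
    if fmt == "xyz":
        comment = f"charge={mol.total_charge} genff-{__version__}"
        if mol.title:
            comment += f" {mol.title}"
        text = _xyz_body(mol, comment)
    elif fmt == "coord":
        rows = ["$coord"]
        for sym, xyz in zip(mol.symbols, mol.coords_bohr):
            rows.append(
                f" {xyz[0]:20.14f} {xyz[1]:20.14f} {xyz[2]:20.14f}  {sym.lower()}"
            )
        rows.append("$end")
        text = "\n".join(rows) + "\n"
    elif fmt == "pdb":
        rows = []
        for i, (sym, (x, y, z)) in enumerate(zip(mol.symbols, mol.coords), start=1):
            rows.append(
                f"HETATM{i:>5d} {sym:>3s}  UNL A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {sym:>2s}"
            )
        rows.append("END")
        text = "\n".join(rows) + "\n"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_trajectory(traj, path) -> None:
    """Write an MD trajectory as multi-frame XYZ.

    Each comment line carries the step index, potential energy (Hartree) and
    instantaneous temperature (K).
    """
    frames = getattr(traj, "frames", traj)
    if len(frames) < 1:
        raise TrajectoryError("trajectory has no frames")
    zs = np.asarray(traj.atomic_numbers, dtype=int)
    syms = [SYMBOLS[z - 1] for z in zs]
    with open(path, "w") as fh:
        for fr in frames:
            xyz = np.asarray(fr.coords_bohr) * ANGSTROM_PER_BOHR
            if xyz.shape[0] != len(zs):
                raise TrajectoryError(
                    f"frame {fr.step} has {xyz.shape[0]} atoms, expected {len(zs)}"
                )
            fh.write(f"{len(zs)}\n")
            fh.write(
                f"step={fr.step} epot={fr.e_pot!r} ekin={fr.e_kin!r} "
                f"T={fr.temperature!r}\n"
            )
            for sym, (x, y, z) in zip(syms, xyz):
                fh.write(f"{sym:<2s} {x:20.12f} {y:20.12f} {z:20.12f}\n")


def read_trajectory_frames(path):
    """Re-parse a multi-XYZ trajectory; yields (coords_A, metadata dict)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frames = []
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        meta = {}
        for tok in lines[i + 1].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                try:
                    meta[k] = float(v)
                except ValueError:
                    meta[k] = v
        xyz = np.array(
            [[float(p) for p in lines[i + 2 + k].split()[1:4]] for k in range(n)]
        )
        frames.append((xyz, meta))
        i += 2 + n
    return frames
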