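"""Unit conversions and physical constants.

Internal units throughout the package are atomic units: Bohr for length,
Hartree for energy, electron masses for mass, and the atomic unit of time
(~0.0242 fs) for dynamics.  File formats use the conventional units of the
format (XYZ/PDB in Angstrom, Turbomole coord in Bohr); conversion happens at
the I/O boundary only.
"""

from __future__ import annotations

import math

# CODATA 2018
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988
KCALMOL_PER_HARTREE = 627.5094740631
HARTREE_PER_KCALMOL = 1.0 / KCALMOL_PER_HARTREE

# masses
AMU_PER_ELECTRON_MASS = 1.0 / 1822.888486209
ELECTRON_MASS_PER_AMU = 1822.888486209

# time
AU_TIME_FS = 0.0241888432650478  # one atomic time unit in femtoseconds
FS_PER_AU_TIME = AU_TIME_FS
AU_TIME_PER_FS = 1.0 / AU_TIME_FS

# thermodynamics
KB_HARTREE_PER_K = 3.166811563e-6  # Boltzmann constant in Hartree/K

# spectroscopy: sqrt(Hartree/(Bohr^2 m_e)) -> angular frequency in 1/s,
# divided by 2*pi*c gives wavenumbers.  Numerically the conversion from the
# square root of a mass-weighted-Hessian eigenvalue (a.u.) to cm^-1:
_HARTREE_J = 4.3597447222071e-18
_BOHR_M = 0.529177210903e-10
_ME_KG = 9.1093837015e-31
_C_CM_S = 2.99792458e10
WAVENUMBER_PER_SQRT_AU = math.sqrt(_HARTREE_J / (_BOHR_M**2 * _ME_KG)) / (
    2.0 * math.pi * _C_CM_S
)
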