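# genff

A generic, fully automatic force field for molecules.  From Cartesian
coordinates, elemental composition, and total charge alone, `genff` builds
the complete potential — covalent topology, electronegativity-equilibration
(EEQ) charges, Hückel π bond orders, dissociative bonded terms, dispersion,
and hydrogen-/halogen-bond corrections — and drives single-point
evaluations, quasi-Newton geometry optimization, and molecular dynamics.
It is aimed at people who need fast, robust, qualitatively correct
structures and dynamics across the periodic table (Z ≤ 86) without
hand-building topologies or hunting for parameters.

## The model

The total energy splits into bonded and non-covalent parts,

```
E        = E_cov + E_NCI
E_cov    = E_bond + E_bend + E_tors + E_rep,bond + E_abc
E_NCI    = E_IES + E_disp + E_HB + E_XB + E_rep,NCI
```

with, at its core, a *dissociative* Gaussian stretch

```
E_bond = − Σ k_b exp(−α_b (r − r0)²)
```

whose well depth and reference length follow the Hückel bond order of each
bond, EEQ electrostatics `E_IES = Σ χ q + ½ Σ η q² + Σ q q erf(r/γ)/r`
carried by two charge sets (a geometric one and a strictly bond-topology
one), charge-scaled C6/C8 dispersion with Becke–Johnson damping, and
directional HB/XB corrections with a lone-pair exclusion factor.  Each
element carries exactly 18 parameters; all pair quantities come from
combination rules.  See `docs/methods.md` for the full account, including
what the shipped parameterization is (and is not) fitted to.

## Worked example

```
$ python -c "
from genff.analysis import generate_fixture
from genff.io import write_structure
write_structure(generate_fixture('water'), 'xyz', 'water.xyz')"
$ genff opt water.xyz --out wopt.xyz
cycles=3 converged=True E=-0.2771011768 |g|=1.712e-05
$ genff sp wopt.xyz --verbose
E(total)  = -0.2771011768 Hartree
  e_bond     = -0.2781880640
  ...
$ genff charges water.xyz
# idx elem      CN        q (geometry)
    0    O    0.9399  -0.34159
    1    H    0.4700  +0.17080
    2    H    0.4700  +0.17080
# sum(q) = +0.0000000000
$ genff freq wopt.xyz
-0.0 -0.0 0.0 0.0 0.0 0.0 1829.5 4128.9 4230.0
```

Reading this: the idealized water input relaxes in 3 cycles to the force
field's own minimum (O–H 0.970 Å, ∠HOH 110.5°); the oxygen carries −0.34 e
with the constraint Σq = 0 satisfied exactly; the harmonic analysis shows
six near-zero rigid-body modes and three real vibrations — one bend near
1830 cm⁻¹ and two O–H stretches near 4130/4230 cm⁻¹, the physically
expected pattern for water.

Other entry points: `genff md` (velocity-Verlet dynamics with seeded,
bit-reproducible velocities), `genff topo` (perceived bonds, rings, π bond
orders as JSON), `genff rmsd` (Kabsch superposition), `genff dist`
(distance/angle distributions over a trajectory), `genff params dump|fit`
(parameter table and refitting harness).  The library API mirrors the CLI:
`ForceField`, `optimize_geometry`, `run_md`, `harmonic_frequencies`,
`perceive_topology`, `solve_eeq`, `generate_fixture`.

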