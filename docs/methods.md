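# Methods

`genff` implements a generic, fully automatic classical force field of the
tight-binding-derived kind: the only user input is Cartesian coordinates,
the elemental composition, and the total molecular charge.  Everything else — the covalent topology, atomic partial
charges, π bond orders, and every force constant — is constructed
automatically.  This note records the model, its assumptions, the default
parameterization, and the numerical choices, in the package's own terms.
The shipped parameter set is our own; no published force-field parameter
values are reproduced or claimed.

## Total energy

The potential is a sum of a covalent and a non-covalent part,

    E = E_cov + E_NCI
    E_cov = E_bond + E_bend + E_tors + E_rep,bond + E_abc
    E_NCI = E_IES + E_disp + E_HB + E_XB + E_rep,NCI

evaluated in atomic units (Bohr, Hartree) on a topology that is perceived
once and then frozen: energies and gradients never re-perceive bonds during
optimization or dynamics.  The potential is *non-reactive* in its term
lists but *dissociative* in its functional forms — every bonded term decays
smoothly to zero as any participating bond is stretched, so fragments can
separate cleanly and a fragment moved to infinity contributes exactly
nothing to the covalent energy of the rest.

## Topology perception

* **Bonds**: atoms i, j are bonded iff `r_ij < f_bond (r_cov,i + r_cov,j)`
  with `f_bond = 1.25` over tabulated single-bond covalent radii.  Atoms
  exceeding a period-dependent neighbor limit (2 for H/He, 4 for the first
  row, 6 beyond, 8 in the d block) have their longest excess bonds pruned;
  ties break toward the lower index pair, making perception deterministic.
* **Coordination numbers**: the smooth logistic count
  `CN_i = Σ_j 1/(1 + exp(−k_cn((r_cov,i+r_cov,j)/r_ij − 1)))`, `k_cn = 16`.
  It is exactly ½ per neighbor at the covalent-radius sum.
* **Angles/torsions** are enumerated exhaustively from the bond graph;
  **rings** come from a minimum cycle basis truncated at size 8 (larger
  cycles get no ring treatment — only small-ring angle corrections are
  used).  **Fragments** are the connected components.
* **Hybridization** is assigned from neighbor counts plus angle sums
  (a 3-coordinate C/N with angle sum near 360° is sp2; a 2-coordinate
  center with an angle above 160° is sp).  It controls reference angles,
  torsion multiplicities, and π-system membership.

## π systems and Hückel bond orders

sp2/sp atoms of B, C, N, O, S with at least one unsaturated neighbor form
conjugated subsystems.  Each subsystem is diagonalized in a Hückel model
with on-site energies `α_i − k_q q_i` (the EEQ topology charges couple into
the diagonal, `k_q = 0.2`) and a constant resonance integral per element
pair (arithmetic mean of the two elements' β).  Using distance-independent
β keeps the closed-form textbook results exact on idealized geometries:
ethylene p = 1, butadiene 0.894/0.447, benzene 2/3 on all six bonds.
π-electron counting: one per sp2/sp carbon, two for three-coordinate
(pyrrole-type) N and for divalent O/S, one for two-coordinate N and
carbonyl O, adjusted by the rounded topology charge; an odd count fills one
singly-occupied level with a warning.  Orbitals are filled aufbau, two per
level, and the π bond order is the off-diagonal density-matrix element.
Bond orders, reference lengths, and topology charges are iterated to a
fixed point (tolerance 1e-6 on the orders, at most 50 sweeps; on
non-convergence the last iterate is used with a warning).  The final bond
order is `1 + p_ij`.

## EEQ charges

Charges minimize

    E(q) = Σ_i (χ_i^eff q_i + ½ η_i q_i²) + Σ_{i<j} q_i q_j A_ij ,
    Σ_i q_i = Q_total

solved as one symmetric (N+1)×(N+1) bordered linear system.  The kernel is
the Gaussian-damped Coulomb interaction `A_ij = erf(r_ij/γ_ij)/r_ij`,
`γ_ij = √(γ_i² + γ_j²)`, finite at r → 0.  `χ^eff = χ + c_cn √CN` with a
small negative `c_cn` (electronegativity drops slightly with coordination).
The sign convention is the standard one: the more electronegative atom of a
heteronuclear pair acquires negative charge.

Two charge sets are used:

* the **geometry set** (smooth function of coordinates) enters the
  electrostatic energy and its linear response enters the gradient;
* the **topology set** replaces r_ij by bond-path distances (sum of
  reference bond lengths along the shortest path, no interaction beyond six
  bonds) and uses integer neighbor counts for CN, so it is exactly
  invariant under any coordinate change that preserves the bond graph.  It
  scales the dispersion coefficients, the HB/XB strengths, and the Hückel
  diagonal, which keeps all of those couplings geometry-constant and their
  gradients trivial.

The electrostatic energy is the EEQ functional evaluated with the damped
kernel over *all* pairs (bonded included) at the mixed charges
`q = ½(q_geom + q_topo)`; the mixing injects the bond-topology set's
polarization response into the electrostatics.  Because the mixed charges
do not minimize the functional, the gradient carries an exact adjoint
(charge-response) term — one extra solve with the already-factorized EEQ
matrix per gradient evaluation.  Positive definiteness of the EEQ matrix is
guaranteed by construction: the default hardnesses are the Gaussian
self-interaction floor `√(2/π)/γ` plus a chemical offset.  A condition
number above 1e12 (e.g. duplicate atoms) raises an ill-conditioned error
carrying the estimate.

## Covalent terms

* **Stretch**: `E = −k_b exp(−α_b (r − r0)²)` — a Gaussian well of depth
  k_b at r0, harmonic force constant `2 k_b α_b`, vanishing at large r
  (bond cleavage costs exactly k_b).  `k_b = √(k_A k_B)·BO^0.8`,
  `α_b` the arithmetic mean, and
  `r0 = r_cov,A + r_cov,B + c_en|ΔEN| − c_bo ln BO` with `c_en = −0.04` Å
  per Pauling unit (polar bonds contract) and `c_bo = 0.08` Å (π bonds
  contract with bond order while their wells deepen).
* **Bend**: `k_θ d(r_1) d(r_2) (cos θ0 − cos θ)²`, reference angles from
  hybridization (109.47°/120°/180°, 60°/90° in 3-/4-rings).  The cosine
  form is nonsingular at 180°; `d(r)` is a logistic damp (≈1 at r0, onset
  1.5 r0, steepness 8) that extinguishes the term when an arm dissociates.
* **Torsion**: `k_φ d(r_1)d(r_2)d(r_3) sin²θ_1 sin²θ_2 (1 + cos(nφ − φ0))`
  expressed entirely in cos φ via the bond normals, hence polynomial in the
  coordinates and singularity-free; the sin² factors of the flanking angles
  smoothly remove torsions with collinear arms.  sp3–sp3 central bonds use
  n = 3 with the staggered arrangement as minimum; π/sp2–sp2 bonds use
  n = 2 with planar minima and a barrier `k_tors_pi·max(BO−1, 0.2)` that
  grows with the Hückel bond order.
* **Bonded repulsion**: `z_i z_j/r · exp(−√(α_i α_j) r^{3/2})` — a
  Coulomb-like wall, strictly positive and monotone.
* **Three-body correction**: over bonded triples A–B–C,
  `−k3 k_AB k_BC exp(−α_AB Δr_AB²) exp(−α_BC Δr_BC²) cos²θ`, a small
  (k3 = 0.02) stabilizing coupling beyond the pairwise sum that inherits
  the stretch Gaussians and therefore dies with either bond.

## Non-covalent terms

The pair list excludes 1,2 and 1,3 pairs, scales 1,4 pairs by 0.5, and is
derived solely from the frozen topology (electrostatics is the exception:
it runs over all pairs, as the EEQ model carries the entire electrostatic
energy).

* **Dispersion**: two-term `−s6 C6/(r⁶+(a1 R0+a2)⁶) − s8 C8/(r⁸+(a1 R0+a2)⁸)`
  with Becke–Johnson rational damping (`s6 = 1, s8 = 1.5, a1 = 0.45,
  a2 = 4 Bohr`).  `C6` per atom is the free-atom reference scaled by the
  charge function `ζ(q) = exp(3(1 − e^q))` capped at 3 — monotone
  decreasing, ζ(0) = 1, anions gain and cations lose dispersion — applied
  to the topology charges.  `C8 = 3 C6 √(Q_i Q_j)` with `Q = α_pol^{2/3}`
  as the size proxy, and `R0 = √(C8/C6)`.
* **HB/XB corrections**: over donor triples A–H⋯B (A, B ∈ {N,O,F,S,Cl})
  and σ-hole triples R–X⋯B (X ∈ {Cl,Br,I} with exactly one covalent
  partner): `−k S_AB f_dist f_ang f_lp` where `S_AB` combines the element
  donor/acceptor strengths with the charge factor `exp(k_gq(q_H − q_B))`
  (stronger for a more positive hydrogen and a more negative acceptor),
  `f_dist` is a Gaussian well centered at twice the covalent-radius sum,
  `f_ang = cos⁴θ` clipped to zero below 90° (the clip joins with zero
  slope), and the lone-pair exclusion `f_lp = Π_C sin²(∠C–B⋯H)` over the
  acceptor's neighbors suppresses approach along B's existing bonds.
  `k_hb = 0.0025 Hartree` places the idealized water dimer at ≈ −3.7
  kcal/mol of HB correction and ≈ −6 kcal/mol total interaction energy,
  the canonical magnitude for one O–H⋯O contact.
* **Non-bonded repulsion**: the bonded wall's functional family with an
  independent global scale (0.5) and softer exponent (0.6).

Repulsion (25 Bohr) and dispersion (40 Bohr) are truncated by shifted-force:
energy and radial derivative are exactly zero at the cutoff and the total
potential stays C¹-smooth; the HB Gaussian is below 1e-16 at its 15 Bohr
cutoff.  The untruncated dispersion kernel is exposed separately
(`dispersion_pair_energy`) and reduces to the plain undamped sum at long
range.  All pair loops are explicitly O(N²); an evaluation counter asserts
the quadratic bound in the tests.

## Optimizer

Quasi-Newton minimization in Cartesian coordinates: an initial Hessian from
central differences of the analytic gradient, assembled *fragment-blocked*
(per covalent fragment, breadth-first split above 300 atoms, inter-block
coupling zeroed) or dense (the test oracle); eigenvalue-shifted Newton
steps inside a trust radius; backtracking line search so accepted steps
never raise the energy (the energy trace is monotone non-increasing by
construction); BFGS updates between steps.  Defaults: ΔE < 5e-6 Hartree
and |g| < 1e-3 Hartree/Bohr, 500 cycles.  Non-convergence returns a result
flagged unconverged (CLI exit code 3), never an exception.  Cartesian
coordinates were chosen over internals for robustness on disconnected
fragments (host–guest situations); the rigid-body null space is handled by
the spectral shift.

## Dynamics and frequencies

Velocity-Verlet in atomic units; Maxwell–Boltzmann initial velocities from
a seeded generator (bit-reproducible; exactly zero at 0 K), center-of-mass
motion removed, temperature from 3N−6 (3N−5 linear) degrees of freedom.
Thermostats: none (NVE), Berendsen (τ = 100 fs; deterministic but not a
canonical ensemble — documented limitation), or periodic rescale.  A
potential energy above 1e4 Hartree in magnitude, or a non-finite value,
aborts the run with the last recorded frame attached.  With the exact
analytic gradients, NVE on water at 0.5 fs conserves total energy to
better than 5e-5 Hartree over 20 000 steps.

Harmonic frequencies come from central differences of the analytic
gradient (step 0.005 Bohr), mass-weighted, with rigid translations and
rotations projected out; the full 3N spectrum is returned (projected modes
appear near zero) and imaginary modes are reported as negative
wavenumbers.  A stretch-only diatomic reproduces the closed form
`ν = √(2 k_b α_b/μ)/(2πc)` to better than 0.1%.

## Parameterization and fitting

Each element carries exactly 18 parameters (asserted in the schema); there
are no element-pair parameters anywhere — all pair quantities come from
combination rules (geometric means for well depths and C6, arithmetic
means for radii and exponents) plus named global scalars.  Defaults are
derived from tabulated covalent radii, Pauling electronegativities, and
free-atom polarizabilities; C6 references are curated for the fit set
(H, C, N, O, F, Na, P, S, Cl, plus rare gases and heavy halogens) and
estimated by a London-type rule elsewhere.  Elements outside the curated
set are flagged `unfitted` in the table metadata: the architecture covers
Z ≤ 86, but only the curated subset has been sanity-tuned (water geometry
and frequencies, hydrocarbon torsion barriers, dimer energetics).  An
exhaustive fit against quantum-chemical references for every element is
outside this package's scope.

The fitting harness is damped least squares (Levenberg–Marquardt /
trust-region-reflective with numerical Jacobians) over any named subset of
element or global parameters, against targets that the package itself can
compute from fixture molecules: optimized bond lengths, optimized angles,
and fixed-geometry energy differences (`coords_b` in Bohr).  Accepted
iterations never increase the residual; a non-finite residual raises a
fitting-diverged error carrying the offending parameter vector.
Self-generated targets give zero residual and return the table unchanged;
the perturb-and-refit identity (generate targets, perturb one parameter,
refit it) recovers the original value to 1e-4 relative and is the
harness's standing regression test.

## The fixture generator

The built-in molecules (water, ammonia, methane, ethane, ethylene,
butadiene, benzene, water dimer, HF dimer, NaCl, helium dimer,
glycylglycine) are constructed from textbook equilibrium values — bond
lengths, angles, the 2.976 Å O⋯O separation of the water dimer with a
near-linear hydrogen bond and a properly tilted acceptor.  They emulate
clean gas-phase equilibrium structures only: no conformational diversity,
no thermal distortion, no condensed-phase environment, no elements beyond
the curated set.  Tests passing on them demonstrate correctness of the
machinery (topology, charges, gradients, integrators) and physically sane
magnitudes, not accuracy against experimental or quantum-chemical data for
arbitrary systems.

## Numerical choices and degenerate inputs

Logistic and Gaussian exponents are clipped before exponentiation
(overflow-safe); the erf kernel uses its analytic r → 0 limit; √CN uses a
1e-30 floor so the CN chain rule stays defined for isolated atoms;
torsions with nearly collinear arms (|n|² < 1e-12) are skipped — their
damped contribution is below 1e-18.  Degenerate Hückel shells filled
partially would break symmetry; the fixtures avoid open degenerate shells
and an odd electron count warns.  Atom pairs closer than 0.25 Å warn (not
error) at load time.  Determinism: identical inputs give byte-identical
topologies, energies, and (per seed) trajectories.

## Known limitations

No implicit solvation, no periodic boundary conditions, no open-shell
states, no bond-topology changes during dynamics, Berendsen is not
canonical, and elements outside the curated set carry rule-derived
defaults of untested accuracy.  The input structure must be reasonably
close to a normal bonding situation for perception to work — the standing
assumption of any non-reactive force field.
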