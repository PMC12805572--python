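# Methods

## Problem

In nonadiabatic simulations of charge transport through molecular solids, the
diagonal of the site-basis Hamiltonian consists of *site energies*: the
classical potential energy of the configuration in which molecule *k* carries
the excess charge and every other molecule is neutral.  A supercell of
`N_mol` molecules therefore requires `N_mol` electrostatic summations *per MD
time step*.  Done brute-force this multiplies the cost of a single summation
by `N_mol` and quickly becomes the bottleneck.  sitefield implements an
addition-subtraction scheme that computes all `N_mol` single-molecule charge
states at a system-size-independent overhead over one summation, together
with the machinery needed to validate it and to use its output (MD engine,
reorganization-energy estimators, site-basis propagation).

## Electrostatic models

**Ewald summation** (module `ewald`) is the exact reference: the
conditionally convergent Coulomb lattice sum is split into a real-space sum
with kernel `erfc(η r)/r` truncated at `r_cut_real`, a reciprocal-space sum
over `0 < |k| ≤ k_max`, the self term `−(η/√π)Σq²` and, for a net cell
charge `q`, the neutralizing-background constant `−q²π/(2η²V)` (tinfoil
boundary conditions; the surface dipole term is absent).  The defaults
η = 0.35 Å⁻¹, `r_cut_real` = 9.6 Å, `k_max` = 1.0 Å⁻¹ are the package's
standard operating point; `ewald.converged_params(η)` instead derives both
cutoffs from a requested kernel decay (`erfc(ηr)/r` and `exp(−k²/4η²)`
below ≈1e-9) and is used wherever the exact, η-independent value is needed
(lattice-constant validation, η-invariance checks).  The k-vector set is the
full sphere with no inversion-symmetry halving — this module is the oracle
and is written for transparency, not speed.  The background constant is
included by default whenever the state carries net charge, because per-state
*absolute* energies are reported; it cancels identically in differences
between states of equal net charge (asserted in the tests).

**Damped shifted force** (module `dsf`) replaces the full periodic sum by a
purely pairwise real-space kernel: the erfc-damped Coulomb interaction
shifted so that both the potential and its radial derivative go continuously
to zero at `r_cut`.  Defaults α = 0.09 Å⁻¹ and `r_cut` = 16 Å; α = 0
selects the undamped shifted-force limit.  A Wolf-style self term
`−[erfc(αR_c)/2R_c + α/√π]Σq²` is available behind
`include_self_term` (default off, because the pairwise sum as defined here
has no self term).  The flag matters for multistate work: the charge sets of
the neutral and charged molecule differ, so the self term shifts per-state
absolute energies while cancelling in same-composition differences.  Both
settings are supported and tested; the addition-subtraction corrections
include the matching per-state self-term change when the flag is on.

Periodic images are enumerated explicitly in both modules (no minimum-image
convention), so cutoffs larger than half the box length are valid — the
16 Å DSF cutoff exceeds L/2 for the smaller test cells.

## The addition-subtraction scheme (module `multistate`)

The all-neutral reference energy is computed once.  For state *I* (molecule
*I* charged) two corrections restricted to pairs touching molecule *I* are
added:

* intramolecular: `Σ (q_i^c q_j^c − q_i^n q_j^n)·R(r_ij)` over pairs inside
  molecule *I* (including its periodic self-images);
* intermolecular: `Σ (q_i^c − q_i^n) q_j^n·R(r_ij)` over pairs with exactly
  one end in molecule *I*.

Both touch `O(N_apm · N_cut)` pairs, so all `N_mol` states cost a constant
multiple (≈3× in pair count for the shipped fixtures) of a single-state
summation — `O(N_mol⁰)` overhead.  The same decomposition gives the DSF
forces for the active state.  For Ewald the real-space part follows the same
recipe; the reciprocal energy re-uses the cached all-neutral structure
factor `A(k)` and per state adds only the `N_apm`-term update
`B_I(k) = Σ_{i∈I} (q_i^c − q_i^n) e^{ik·R_i}`.  The per-state self-term
change `−(η/√π)Σ_{i∈I}(q_i^c² − q_i^n²)` and the per-state background
constant are included as well — without them the scheme would not reproduce
the brute-force per-state energies it is defined to equal.

**Pair-counting convention.**  All sums count each (home atom *i*, atom *j*
in image **n**) interaction once per unit cell, equivalent to the
conventional `½ΣΣΣ'` double count.  One published form of the intermolecular
correction carries a `½(1+δ_n0)` prefactor, which for **n** ≠ **0** images
evaluates to half the value this convention (and brute-force equivalence)
requires.  The implementation is derived from first principles — count each
interaction once — and is validated against the brute-force oracle to
1e-10 relative on every state across seeded fixtures; that equivalence, not
any printed prefactor, is the ground truth here.

**Reciprocal-space forces.**  The pairwise sine form of the per-state
reciprocal forces is implemented literally (`addsub_ewald_recip_forces`),
size-guarded, and cross-checked against the structure-factor derivative.
Its cost is `O(N_k N_at²)` because the scalar products `k·R_kj` must be
recomputed for every atom: this is precisely why the addition-subtraction
scheme pays off for DSF energies *and* forces but only for Ewald *energies*.
The production reciprocal forces use the `O(N_k N_at)` structure-factor
derivative.

**Scaling report.**  Cost is measured in pair-evaluation counts, not wall
clock: counts are deterministic, hardware-independent and reproduce the
scaling argument directly.  On toy crystals of 32, 108 and 256 molecules
the all-states DSF count has log-log slope ≈ 1.0 against system size with a
flat overhead ratio ≈ 3.0, while the brute-force count has slope ≈ 2.

## Exclusion policy

Intramolecular electrostatic pairs are fully included (no 1-2/1-3
force-field exclusions): the summations implement the literal lattice sums
above.  Because the intramolecular correction of the addition-subtraction
scheme uses the same convention as the brute-force path, the equivalence is
unaffected by this choice; an exclusion scheme would be a property of the
force field, not of the summation method, and is out of scope.

## Toy force field and MD engine (module `md`)

The MD engine exists to exercise the electrostatics end-to-end: NVE energy
conservation, thermal ensembles, and finite-temperature gap sampling.

* Harmonic bonds with per-state equilibrium lengths
  `r⁰c = r⁰n + β·Δr` (β = 0.88 by default — the bond-displacement scaling
  used when fitting a charged-state force field to quantum-chemical
  displacements).
* Optional shifted-force Lennard-Jones between atoms of different molecules
  (parameters live in the fixtures, not the engine), so toy lattices are
  mechanically stable.
* Velocity Verlet, default dt = 1 fs; masses from a small internal element
  table.  A Verlet neighbour list with a 1 Å skin is rebuilt whenever any
  atom has moved more than half the skin; kernels always evaluate distances
  from current positions, and pairs beyond the cutoff contribute exactly
  zero, so the cached list never changes the forces — energy conservation
  is preserved by construction.
* NVT uses stochastic velocity rescaling (Bussi) rather than Nosé–Hoover:
  it samples the canonical ensemble correctly with a single time-constant
  parameter and no chain bookkeeping.  This is a deliberate substitution and
  the only thermostat provided.
* For the NVE benchmark with Ewald forces the real-space cutoff is raised
  from 9.6 to 11 Å: the truncation step of `erfc(ηr)/r` at the cutoff
  (≈1e-7 eV per pair crossing at 9.6 Å) would otherwise contribute noise
  near the drift bound being tested.  This is a numerical-convergence
  choice, not a change of model.

Observed NVE drift on the 32-molecule toy crystal (10 ps, dt = 1 fs) is
≈3e-7 eV·atom⁻¹·ps⁻¹ for both DSF and Ewald forces.

## Error metrics (module `reorg`)

`error_metrics` reports MUE/MUF and max/MUF as percentages, where MUE is the
mean unsigned deviation of the test series from the reference, MUF the mean
unsigned fluctuation of the reference about its own mean.  Both series are
first centered on their own means by default (`center=False` disables
this): the metric then measures how faithfully the *fluctuations* are
reproduced, which is the quantity that matters for dynamics and for
reorganization energies; a constant offset between two summation schemes
(e.g. from shift and self terms) affects neither.  This centering is a
stated convention of this package.  On the shipped 50-snapshot toy-crystal
ensemble the DSF energy fluctuation error against Ewald falls monotonically
with `r_cut` and is ≈0.1 % at the 16 Å / 0.09 Å⁻¹ operating point —
comfortably below the 5 % acceptance bound.

## Reorganization energies

Three estimators: λ^st (mean vertical gap on the initial surface; zero
driving force assumed, i.e. self-exchange), λ^var = σ²/(2k_BT), and the
4-point scheme from minimized end states.  λ^st error bars come from block
averaging over 5 equal blocks; the gap variance uses the sample (n−1)
denominator.  λ_o = λ − λ_i uses λ_i^4p for the inner part, neglecting its
weak temperature dependence (documented convention).  The Marcus continuum
expression, the Pekar-factor ratio
`p^c = (1 − 1/ε_s)/(1/ε_op − 1/ε_s)` and the charge-scaling factor
`γ = ε_op^(−1/2)` are provided as desk calculators;
`apply_charge_scaling` builds scaled charge sets `q̃^n = γq^n`,
`q̃^c = γq^n + Δq` whose net molecular charge is exactly preserved for any
γ because `Σq^n = 0` and `ΣΔq = q`.

## Transport (module `transport`)

Propagation is strictly diabatic: iħu̇ = H(t)u with the supplied site-basis
Hamiltonian, RK4 with electronic substep δt = Δt/5 by default and linear
interpolation of H between frames.  The nonadiabatic couplings d_kl that
arise from nuclear motion of the orbital basis are set to zero — this
module operates on given H(t) trajectories (model chains, or site energies
from the multistate module) and does not construct the orbital machinery.
The norm is monitored, never silently renormalized; its drift scales as
(|H|δt/ħ)⁶ per substep and stays below 1e-8/ps for Hamiltonian scales of
tens of meV at the default substep.

A minimal fewest-switches hopping step is provided for model studies: time
derivative couplings are estimated from eigenvector overlaps of consecutive
frames, degenerate eigenvalues are ordered by value and then by
largest-amplitude site index with overlap signs fixed positive, hop
probabilities are clipped to [0, 1], and hops are accepted without velocity
adjustment (no nuclear back-reaction).  Decoherence corrections,
trivial-crossing tracking and velocity rescaling are out of scope.

Observables: IPR (1 ≤ IPR ≤ N), MSD tensor from site populations and site
positions (site position = molecular center of mass when derived from a
crystal), diffusion from the best linear fit of the MSD discarding the first
20 % of the series (configurable), mobility from the Einstein relation
μ = eD/k_BT (thermal voltage 0.0258520 V at 300 K).

## Synthetic systems (module `fixtures`)

All generators are pure functions of (parameters, seed).

* **Rock-salt lattice** (±1 e ions, one ion pair per "molecule"): validates
  the Ewald oracle against the Madelung constant 1.747565.
* **Wigner lattice** (single +1 e charge with neutralizing background in a
  cubic cell): validates the background term against the simple-cubic
  constant 1.418649 (= 2.837297/2).
* **Toy molecular crystal**: an fcc lattice (4 molecules per cubic cell,
  lattice constant 7 Å) of planar 4-atom molecules with seeded random
  orientations, neutral charges (−0.30, 0.14, 0.10, 0.06) e summing to zero
  (dipolar pattern) and charged-state increments (0.40, 0.20, 0.20, 0.20) e
  summing to +1 e; harmonic bonds (k = 20 eV/Å², r⁰n = 1.10 Å,
  Δr = 0.05 Å, β = 0.88).  The 4-atom molecule deliberately replaces a
  literal polyacene: it keeps `N_apm` small while preserving the
  neutral-dipolar/charged-monopolar structure that exercises both
  correction classes of the addition-subtraction scheme.  What it does
  *not* emulate: realistic molecular geometry, charge distributions fit to
  quantum chemistry, van-der-Waals anisotropy, or lattice dynamics of a
  real crystal — passing tests demonstrate correctness of the summation
  algebra and the method's error systematics, not force-field accuracy for
  any real material.
* **Thermal snapshot ensembles** via isotropic Gaussian displacements of
  requested RMS amplitude (0.15 Å in the shipped benchmarks) — a stand-in
  for MD sampling that preserves determinism and speed.
* **Gap series**: Gaussian gaps with mean λ and, under linear response,
  variance 2k_BTλ, so the Stokes and variance estimators must agree.
* **Hamiltonian chain**: nearest-neighbour chain (constant coupling J,
  5 Å spacing) with independent stationary Ornstein–Uhlenbeck site-energy
  noise of stated σ and correlation time — the simplest stationary
  correlated process, sufficient for the qualitative disorder experiment
  (σ = 0.05 eV strictly lowers steady-state IPR and fitted mobility
  relative to σ = 0 on the same seeds).

## Problem sizes used in the shipped benchmarks

Exactness: 20 seeded 24-molecule crystals (96 atoms).  Scaling: 32, 108,
256 molecules.  DSF accuracy: 50 snapshots of the 32-molecule crystal.
Energy conservation: 10 ps NVE, 32 molecules, both methods.  Transport
disorder check: 40-site chain, 0.6 ps, 6 noise realizations.  These sizes
were chosen so the full validation runs on a single CPU in minutes while
every claim (oracle equivalence, counter scaling, error saturation, drift
bound, disorder direction) is exercised at a size where its failure mode
would be visible.

## Known limitations

* No mesh Ewald (PME/SPME); the brute-force Ewald oracle is `O(N²)`-ish by
  design and not intended for production MD.
* Single-molecule charge states only; charge-transfer pair states (two
  molecules differing) are not supported.
* The DSF accuracy numbers quoted here are properties of the toy fixtures;
  for a real material they must be re-measured for that system's charge
  distribution and density.
* The MD engine has no constraints, no pressure coupling, and a
  deliberately small element table.
* Strictly diabatic propagation ignores basis-motion nonadiabaticity; the
  hopping mode has no back-reaction, so detailed balance between surfaces
  is not enforced.
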