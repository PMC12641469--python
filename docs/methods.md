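# Methods

## Model and procedure

The package computes alchemical free energy differences for systems
described by a cutoff-based pair potential whose only view of the system
is its neighbor list: the unordered atom pairs with minimum-image
distance *d* < *r*<sub>cut</sub>, each entry carrying its distance and
displacement. Two list-level operations implement all alchemistry:

* **Masking** removes every entry with an endpoint in a masked set.
  Because the potential contract forbids any dependence on atoms outside
  the list, masking is *exactly* equivalent to deleting the atom — an
  invariant the suite asserts to machine precision.
* **λ-shifting** replaces the distance of selected entries by
  d⁽ᵏ⁾(λ), k ∈ {1..4} (see README table). Pairs whose shifted distance
  reaches *r*<sub>cut</sub> are dropped from the list rather than kept at
  a long distance; for a potential that vanishes continuously at the
  cutoff this is exact and reproduces the fully decoupled end state (the
  pairs are simply absent).

The default pair selector modifies exactly the solute–solvent cross
pairs (absolute decoupling); a per-atom selector supports dual-topology
relative transformations. Intrasolute and solvent–solvent entries are
never touched, so the gas-phase leg of an absolute solvation cycle is
identically zero — the ASFE protocol verifies this zero at run time
instead of assuming it.

**The ε guard.** Schemes 2 and 4 shift *to* the cutoff and need a small
excess ε > 0 so that rounding cannot leave a pair marginally inside the
list at λ = 1. The guard is scaled as λ·ε: the two end-state properties
— exact identity at λ = 0 and strict cutoff clearance at λ = 1 — then
hold simultaneously. Default ε = 1e-4 Å, generous for single precision
yet negligible (the potential is identically zero well before
*r*<sub>cut</sub> − ε matters). All arithmetic here is double precision.

**Forces.** The modified distance depends on coordinates only through
the true distance, so forces need one extra factor, the chain factor
∂d′/∂d per entry (1 for unmodified pairs; (1 − λ) for scheme 2; d/d′ for
scheme 3; analogous for 4). The fictitious-dimension offset itself
carries no force component. At d = 0 schemes 3/4 use the limiting factor
0 (for λ > 0) rather than raising. Analytic forces are validated against
central finite differences at 1e-5 relative tolerance for every scheme
and λ.

## Potential backends

The backend contract (`PotentialModel`) requires vectorised per-pair
energies/derivatives given species and (possibly modified) distance,
continuity, and energy → 0 as d → *r*<sub>cut</sub>. Two concrete
backends are provided:

* `ToyPairPotential` — Lennard-Jones 12-6 with Lorentz–Berthelot
  combining, multiplied by a C¹ cubic switch from 0.8·r_cut to r_cut.
  It stands in for a trained neural network potential; what the method
  relies on is only the list-mediated interface. For genuinely
  many-body potentials a shifted pair distance would enter higher-order
  features as well; the contract covers this, but only the pairwise case
  is verified numerically here.
* `HarmonicPairPotential` — switched springs between specific species
  pairs, used for analytically solvable test systems.

`FlatBottomRestraint` (zero inside radius r0, harmonic 0.5·k(r−r0)²
outside, C¹ at the boundary) keeps weakly coupled atoms near their
sites.

## Sampling

Configurations at each λ-state come from BAOAB-discretised Langevin
dynamics, NVT, neighbor list rebuilt every step (no Verlet skin — at
desk scale correctness beats speed). Defaults: timestep 1 fs, friction
1 ps⁻¹ (a package choice; it only affects sampling efficiency), 300 K,
coordinates saved every few steps. Velocities are drawn fresh from
Maxwell–Boltzmann per window; all randomness uses seeded PCG64, so runs
are bit-reproducible. An isotropic Monte Carlo barostat is available but
off by default: the validation checks (scheme equivalence, cycle
closure) are state-point independent, and NPT adds cost and noise.

On a non-finite force or energy the window runner retries once with a
halved timestep (0.5 fs) and doubled step counts/saving interval, so the
physical length and saved time grid are unchanged; a second failure
raises with the offending atoms named. The toy potential cannot produce
the spontaneous instabilities of learned potentials, so this code path
is exercised in tests by a model that injects a transient force spike.

## Estimation

Fixed-rule subsampling: discard the first 20 % of saved frames (floor),
then keep every 4th of the remainder. No autocorrelation analysis is
applied beyond this fixed rule — a deliberate fidelity choice matching
the production protocol the package emulates (4000 saved frames → 800
retained per λ-state).

**BAR** between neighbouring λ-states is the production estimator; the
self-consistent acceptance-ratio equation is solved by bisection to
|residual| < 1e-10, and per-window results are summed over the schedule.
Leg uncertainties are the sample standard deviation over ≥ 2 independent
repeats (headline errors); the first-order BAR asymptotic error is
reported alongside per window. Tests validate BAR against the
harmonic-oscillator closed form ΔG = (1/2β)·ln(k₁/k₀), against an
independently coded maximum-likelihood route, for exact antisymmetry,
and for lower RMSE than one-sided exponential averaging.

**MBAR** is diagnostic-only. When samples from near-decoupled states are
re-evaluated at strongly coupled states, configurations with solvent
overlapping solute sites can yield unphysically low energies and would
dominate a multistate reweighting estimate. `mbar_with_diagnostics`
attempts the self-consistent solution (returning a report instead of
raising on non-convergence) and flags every sample whose re-evaluated
reduced energy lies more than 50 k_BT (package default; configurable)
below the minimum actually sampled at that state, reporting the share of
the target state's Boltzmann weight the sample would carry.

## λ schedules and protocols

`asfe-15` is the decoupling schedule: λ = i/19 for
i ∈ {0..9, 11, 13, 15, 17, 19} — dense at strong coupling where the
offset grows fastest. Uniform and explicit schedules are supported; no
claim of optimality is made, and the schedule is plain configuration.

**ASFE.** ΔG_solv ≡ −ΔG(couple→decouple in solution). Windows are
chained (each starts from the previous window's final configuration)
with per-window 20 % discard; repeats re-run the whole chain with
independent seeds. The gas leg is verified to be exactly zero.

**RSFE analog.** The relative leg between two end states differing at a
single atom site is computed dual-topology style: both variant atoms are
present; the vanishing one is per-atom decoupled (λ) while the appearing
one runs the reverse (1 − λ); the two copies are permanently hidden from
each other via a masked pair; each is held by a flat-bottom restraint at
its site. The two restraints are identical wells (asserted numerically),
so a decoupled dummy contributes the same restraint partition function
in every phase and the contributions cancel in the cycle. This is a
simplified analog of a tautomer relative-transformation protocol, not a
reproduction of any specific one; the cycle-closure validation is
self-consistent regardless, because both routes use only this package's
own legs. A gas-phase variant with harmonic site energies is checked
against a quadrature closed form.

**Cycle closure.** closure = ΔG_gas + ΔG_solv(T2) − ΔG_aq − ΔG_solv(T1),
with root-sum-of-squares error propagation from the four leg
uncertainties.

## Toy systems (what the generator emulates, and what it does not)

The fixture generator builds a solvation study in miniature:

* Solvent: 50 Lennard-Jones particles (ε 0.20 kcal/mol, σ 3.0 Å, mass
  18 amu) in a 12 Å periodic cube — water-like density — placed by
  seeded rejection sampling (minimum pair distance 0.85 σ) and relaxed
  by steepest descent. Exclusion spheres around the solute sites let the
  embedded system start without overlaps.
* Solute: three core particles (ε 0.30, σ 3.2) in a triangle at LJ
  contact plus one variant particle (ε 0.25, σ 3.0) above the centroid;
  the tautomer-like partner moves the variant particle 1.5 Å sideways.
  The solute is held together by flat-bottom restraints to spatial
  anchors (core r0 0.75 Å, k 20; variant r0 1.0 Å, k 10) rather than by
  bonds: restraints are identical in every leg and at both end states,
  so they cancel in the cycle, and per-atom decoupling of a variant atom
  never has to fight a bonded term.
* Gas phase: the same solute and restraints in a large (50 Å) empty box.

This emulates the *structure* of the real problem — a solute coupled to
a periodic bath, two end states differing at one site, restrained weakly
coupled atoms — but not its chemistry: no electrostatics, no molecular
solvent with internal degrees of freedom, no learned potential
energetics, and window lengths of picoseconds rather than nanoseconds.
Passing tests therefore demonstrate the correctness of the list
manipulation, the sampling machinery and the estimators, not the
accuracy of any real solvation free energy.

## Problem sizes and numerical choices

Desk-scale defaults used by the validation suite (the package's own
choice of scale): 15-window scheme comparisons at 1500 steps/window and
3 repeats; cycle runs over a reduced 12-point schedule (dense at small
λ) at 500 steps/window, 3 repeats, 20 seeds. At these lengths individual
legs carry repeat spreads of order 1 kcal/mol, which the repeat-std
error model propagates honestly into the closure test — closure is a
calibration check, not a precision claim. The BAR bisection tolerance
(1e-10), the MBAR convergence tolerance (1e-8, max 2000 iterations), the
ε guard (1e-4 Å) and the minimum-image requirement box > 2·r_cut are
fixed numerical choices; degenerate inputs (empty lists, single repeats,
zero-distance pairs, masked everything) are defined or rejected
explicitly rather than left to chance.

## Known limitations

Orthorhombic boxes only; no constraints, virtual sites or long-range
electrostatics; no cell lists (O(N²) list build, fine for desk scale);
the NNP backend contract is exercised only by pairwise models; the MC
barostat is provided but unused by the validation suite; the RSFE analog
handles a single variant site (multi-atom appear/disappear would need
masking and decoupling combined).
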