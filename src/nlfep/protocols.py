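"""Free-energy protocols: lambda schedules, ASFE/RSFE legs, cycle closure.

An absolute solvation free energy (ASFE) leg decouples the whole solute
from the solvent by shifting every solute-solvent neighbor-list entry;
because intrasolute interactions are never touched, the corresponding
gas-phase leg is identically zero (this is *verified*, not assumed).  The
relative leg (RSFE analog) is a dual-topology transformation: both variant
atoms are present, the vanishing one is per-atom decoupled from lambda=0
to 1 while the appearing one runs the reverse, each held near its site by
a flat-bottom restraint, and the two variants are permanently hidden from
each other.

The two routes to the same relative free energy close a thermodynamic
cycle::

    closure = dG_gas(T1->T2) + dG_solv(T2) - dG_aq(T1->T2) - dG_solv(T1)

which must vanish within the Gaussian-propagated repeat uncertainties —
an internal correctness check that needs no reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

from .estimation import FreeEnergyResult, bar, subsample, sum_windows
from .neighborlist import AlchemicalSpec, single_atom_selector
from .potentials import FlatBottomRestraint, PotentialModel
from .sampling import SamplerSettings, potential_energy, run_window
from .system import ParticleSystem

__all__ = [
    "LambdaSchedule",
    "make_lambda_schedule",
    "run_asfe",
    "run_rsfe_analog",
    "cycle_closure",
    "CycleLedger",
    "sample_leg",
]

#: The 15-point ASFE schedule, dense at strong coupling: i/19 for
#: i in {0..9, 11, 13, 15, 17, 19}.
ASFE15_NUMERATORS = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 11, 13, 15, 17, 19)


@dataclass(frozen=True)
class LambdaSchedule:
    """Strictly increasing lambda values from 0 to 1."""

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2 or vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("schedule must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def reversed(self) -> tuple:
        return tuple(reversed(self.values))


def make_lambda_schedule(preset: str | None = None, n: int | None = None,
                         values: Sequence[float] | None = None
                         ) -> LambdaSchedule:
    """Build a lambda schedule from a preset, a uniform count, or values.

    ``preset="asfe-15"`` gives the 15-point schedule used for absolute
    decoupling (denser where the offset grows fastest); ``n`` gives a
    uniform schedule; explicit ``values`` are validated verbatim.
    """
    given = sum(x is not None for x in (preset, n, values))
    if given != 1:
        raise ValueError("specify exactly one of preset, n, values")
    if preset is not None:
        if preset != "asfe-15":
            raise ValueError(f"unknown preset {preset!r}")
        return LambdaSchedule(tuple(
            float(Fraction(i, 19)) for i in ASFE15_NUMERATORS))
    if n is not None:
        if n < 2:
            raise ValueError("need at least 2 lambda values")
        return LambdaSchedule(tuple(np.linspace(0.0, 1.0, n)))
    return LambdaSchedule(tuple(values))


def _window_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(int(base_seed)).generate_state(n) % (2 ** 31)


def sample_leg(system: ParticleSystem, model: PotentialModel, spec_factory,
               schedule: LambdaSchedule, settings: SamplerSettings,
               restraints: Sequence = (), seed: int = 0,
               n_equil_steps: int = 0):
    """Sample every window of one leg and return per-window BAR estimates.

    Windows are chained: each starts from the final configuration of the
    previous one (serial lambda-annealing), and the first 20 % of each
    window is discarded as window-specific equilibration before stride-4
    subsampling.  ``spec_factory(lam)`` must return the alchemical spec
    (or spec sequence) of state lam.

    Returns (window_dgs, bar_stderrs), kcal/mol.
    """
    beta = settings.thermo.beta
    lams = schedule.values
    seeds = _window_seeds(seed, len(lams) + 1)

    current = system
    if n_equil_steps > 0:
        eq = replace(settings, n_steps=n_equil_steps,
                     save_interval=n_equil_steps, seed=int(seeds[-1]))
        traj = run_window(current, model, spec_factory(lams[0]), eq,
                          restraints)
        current = system.with_positions(traj.final_positions)

    frames = []
    own_energies = []
    for k, lam in enumerate(lams):
        st = replace(settings, seed=int(seeds[k]))
        traj = run_window(current, model, spec_factory(lam), st, restraints)
        current = system.with_positions(traj.final_positions)
        keep = subsample(traj.n_frames)
        frames.append(traj.frames[keep])
        own_energies.append(traj.energies[keep])

    window_dgs = np.empty(len(lams) - 1)
    stderrs = np.empty(len(lams) - 1)
    for k in range(len(lams) - 1):
        spec_hi = spec_factory(lams[k + 1])
        spec_lo = spec_factory(lams[k])
        u_hi_on_lo = np.array([
            potential_energy(system.with_positions(x), model, spec_hi,
                             restraints)
            for x in frames[k]
        ])
        u_lo_on_hi = np.array([
            potential_energy(system.with_positions(x), model, spec_lo,
                             restraints)
            for x in frames[k + 1]
        ])
        w_f = beta * (u_hi_on_lo - own_energies[k])
        w_r = beta * (u_lo_on_hi - own_energies[k + 1])
        res = bar(w_f, w_r, settings.thermo)
        window_dgs[k] = res.delta_g
        stderrs[k] = res.stderr
    return window_dgs, stderrs


def _verify_gas_leg(gas_system, model, make_spec, schedule, settings,
                    restraints, seed):
    """Check that decoupling does nothing in the gas phase.

    Intrasolute pairs are never shifted, so every window difference must
    be exactly zero; a short gas window is sampled and re-evaluated at all
    lambda values.
    """
    st = replace(settings, n_steps=max(50, settings.n_steps // 10),
                 save_interval=10, seed=int(seed))
    traj = run_window(gas_system, model, make_spec(0.0), st, restraints)
    ref = np.array([
        potential_energy(gas_system.with_positions(x), model,
                         make_spec(0.0), restraints)
        for x in traj.frames
    ])
    for lam in schedule.values:
        u = np.array([
            potential_energy(gas_system.with_positions(x), model,
                             make_spec(lam), restraints)
            for x in traj.frames
        ])
        if not np.array_equal(u, ref):
            raise AssertionError(
                f"gas-phase leg is not invariant at lambda={lam}: "
                "decoupling touched intrasolute interactions"
            )


def run_asfe(solvated: ParticleSystem, gas: ParticleSystem,
             model: PotentialModel, scheme: int, schedule: LambdaSchedule,
             settings: SamplerSettings, n_repeats: int = 3,
             seeds: Sequence[int] | None = None,
             restraints: Sequence = (), gas_restraints: Sequence = (),
             epsilon: float = 1e-4, n_equil_steps: int = 0,
             verify_gas: bool = True) -> FreeEnergyResult:
    """Absolute solvation free energy of the solute in ``solvated``.

    Decouples all solute-solvent cross pairs over the schedule, estimates
    the decoupling free energy by summed pairwise BAR, and returns
    dG_solv = -dG(couple->decouple).  The gas-phase leg is verified to be
    identically zero (unless ``verify_gas=False``).
    """
    if solvated.n_atoms <= gas.n_atoms:
        raise ValueError("solvated system must contain solvent atoms")
    seeds = list(seeds) if seeds is not None else list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")

    def make_spec(lam):
        return AlchemicalSpec(scheme=scheme, lam=lam, epsilon=epsilon)

    if verify_gas:
        _verify_gas_leg(gas, model, make_spec, schedule, settings,
                        gas_restraints, seed=seeds[0] + 91)

    all_windows, all_stderrs = [], []
    for s in seeds:
        dgs, errs = sample_leg(solvated, model, make_spec, schedule,
                               settings, restraints, seed=s,
                               n_equil_steps=n_equil_steps)
        all_windows.append(dgs)
        all_stderrs.append(errs)
    return FreeEnergyResult.from_windows(
        np.array(all_windows), sign=-1.0, estimator="BAR",
        label="dG_solv", bar_stderrs=np.array(all_stderrs),
    )


def _find_variant(t1: ParticleSystem, t2: ParticleSystem) -> int:
    if t1.n_atoms != t2.n_atoms:
        raise ValueError("T1 and T2 must have the same atoms")
    if not np.array_equal(t1.species, t2.species) or \
       not np.allclose(t1.masses, t2.masses):
        raise ValueError("T1 and T2 must share species and masses")
    diff = np.where(np.any(t1.positions != t2.positions, axis=1))[0]
    if len(diff) != 1:
        raise ValueError(
            f"T1 and T2 must differ at exactly one atom site, found "
            f"{len(diff)} differing atoms"
        )
    return int(diff[0])


def run_rsfe_analog(t1: ParticleSystem, t2: ParticleSystem,
                    model: PotentialModel, schedule: LambdaSchedule,
                    settings: SamplerSettings, restraints: Sequence = (),
                    scheme: int = 2, epsilon: float = 1e-4,
                    variant_restraint: dict | None = None,
                    n_repeats: int = 3,
                    seeds: Sequence[int] | None = None,
                    n_equil_steps: int = 0,
                    variant_index: int | None = None) -> FreeEnergyResult:
    """Relative free energy T1 -> T2 in one phase (dual-topology analog).

    Builds a combined system holding the variant atom at both sites; along
    lambda the site-1 copy is per-atom decoupled while the site-2 copy is
    coupled in reverse.  Both copies carry identical flat-bottom restraints
    to their sites (``variant_restraint``: dict with ``r0``, ``kf``), whose
    contributions cancel between the end states; the two copies never see
    each other.  Returns dG(T1->T2) with repeat statistics.
    """
    if variant_index is not None:
        v = int(variant_index)
        if t1.n_atoms != t2.n_atoms:
            raise ValueError("T1 and T2 must have the same atoms")
    else:
        v = _find_variant(t1, t2)
    n = t1.n_atoms
    vr = dict(variant_restraint or {"r0": 1.0, "kf": 10.0})

    dual = ParticleSystem(
        positions=np.vstack([t1.positions, t2.positions[v][None, :]]),
        species=np.append(t1.species, t1.species[v]),
        masses=np.append(t1.masses, t1.masses[v]),
        box=t1.box.copy(),
        solute_indices=t1.solute_indices | {n},
    )
    site1 = t1.positions[v].copy()
    site2 = t2.positions[v].copy()
    r_d1 = FlatBottomRestraint(atom=v, anchor_point=site1, **vr)
    r_d2 = FlatBottomRestraint(atom=n, anchor_point=site2, **vr)
    # Restraint-cancellation symmetry: the two variant restraints must be
    # the same well, just anchored at different sites.
    probe = np.linspace(0.0, 3.0 * vr["r0"] + 1.0, 7)
    e1 = [0.5 * r_d1.kf * max(0.0, r - r_d1.r0) ** 2 for r in probe]
    e2 = [0.5 * r_d2.kf * max(0.0, r - r_d2.r0) ** 2 for r in probe]
    if not np.allclose(e1, e2):
        raise AssertionError("variant restraints are not symmetric")
    all_restraints = tuple(restraints) + (r_d1, r_d2)

    sel_out = single_atom_selector(v)
    sel_in = single_atom_selector(n)

    def make_spec(lam):
        return (
            AlchemicalSpec(scheme=scheme, lam=lam, epsilon=epsilon,
                           pair_selector=sel_out,
                           masked_pairs=frozenset({(v, n)})),
            AlchemicalSpec(scheme=scheme, lam=1.0 - lam, epsilon=epsilon,
                           pair_selector=sel_in),
        )

    seeds = list(seeds) if seeds is not None else list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    all_windows, all_stderrs = [], []
    for s in seeds:
        dgs, errs = sample_leg(dual, model, make_spec, schedule, settings,
                               all_restraints, seed=s,
                               n_equil_steps=n_equil_steps)
        all_windows.append(dgs)
        all_stderrs.append(errs)
    return FreeEnergyResult.from_windows(
        np.array(all_windows), sign=+1.0, estimator="BAR",
        label="dG(T1->T2)", bar_stderrs=np.array(all_stderrs),
    )


@dataclass(frozen=True)
class CycleLedger:
    """Thermodynamic cycle bookkeeping, kcal/mol.

    closure = dG_gas + dG_solv(T2) - dG_aq - dG_solv(T1); the propagated
    error is the root sum of squares of the four leg uncertainties.
    """

    dg_solv_t1: float
    dg_solv_t2: float
    dg_gas: float
    dg_aq: float
    err_solv_t1: float = 0.0
    err_solv_t2: float = 0.0
    err_gas: float = 0.0
    err_aq: float = 0.0

    @property
    def closure(self) -> float:
        return (self.dg_gas + self.dg_solv_t2
                - self.dg_aq - self.dg_solv_t1)

    @property
    def propagated_error(self) -> float:
        return float(np.sqrt(self.err_solv_t1 ** 2 + self.err_solv_t2 ** 2
                             + self.err_gas ** 2 + self.err_aq ** 2))

    def closes(self, n_sigma: float = 2.0) -> bool:
        return abs(self.closure) <= n_sigma * self.propagated_error

    def to_dict(self) -> dict:
        return {
            "dG_solv_T1": [self.dg_solv_t1, self.err_solv_t1],
            "dG_solv_T2": [self.dg_solv_t2, self.err_solv_t2],
            "dG_gas": [self.dg_gas, self.err_gas],
            "dG_aq": [self.dg_aq, self.err_aq],
            "closure": self.closure,
            "propagated_error": self.propagated_error,
        }


def cycle_closure(dg_solv_t1, dg_solv_t2, dg_gas, dg_aq) -> CycleLedger:
    """Assemble a :class:`CycleLedger` from four legs.

    Each leg is ``(value, uncertainty)`` or a :class:`FreeEnergyResult`.
    """
    def unpack(leg):
        if isinstance(leg, FreeEnergyResult):
            return leg.value, leg.stderr
        value, err = leg
        return float(value), float(err)

    v1, e1 = unpack(dg_solv_t1)
    v2, e2 = unpack(dg_solv_t2)
    vg, eg = unpack(dg_gas)
    va, ea = unpack(dg_aq)
    return CycleLedger(dg_solv_t1=v1, dg_solv_t2=v2, dg_gas=vg, dg_aq=va,
                       err_solv_t1=e1, err_solv_t2=e2, err_gas=eg,
                       err_aq=ea)
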