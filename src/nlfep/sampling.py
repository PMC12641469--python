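"""Langevin sampling of alchemical states.

Configurations at each lambda-window are generated with BAOAB-discretised
Langevin dynamics on the alchemically modified potential (neighbor list
rebuilt every step, then masked/shifted, then fed to the potential).  The
window runner implements the practical crash response used for unstable
trajectories: on a non-finite force or energy the window is rerun once
with a halved timestep (saving interval doubled in steps, so the saved
time grid is unchanged) before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import KCAL_MOL_TO_AKMA
from .neighborlist import AlchemicalSpec, apply_alchemy, build_neighbor_list
from .potentials import (PotentialModel, energy, forces, restraint_energy,
                         restraint_forces)
from .system import ParticleSystem, ThermoState

__all__ = [
    "SamplerSettings",
    "Trajectory",
    "InstabilityError",
    "langevin_step",
    "run_window",
    "potential_energy",
    "maxwell_velocities",
    "mc_barostat_move",
]


class InstabilityError(RuntimeError):
    """Raised when the dynamics produce non-finite forces or energies."""

    def __init__(self, message, atoms=()):
        super().__init__(message)
        self.atoms = tuple(atoms)


@dataclass(frozen=True)
class SamplerSettings:
    """Langevin run settings.

    timestep in ps (default 1 fs; the stability fallback is 0.5 fs),
    friction in 1/ps, ``save_interval`` in steps (default the equivalent
    of 0.25 ps at a 1 fs step).
    """

    timestep: float = 0.001
    friction: float = 1.0
    n_steps: int = 1000
    save_interval: int = 250
    seed: int = 0
    thermo: ThermoState = field(default_factory=lambda: ThermoState(300.0))

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Saved frames of one window plus bookkeeping.

    ``frames`` has shape (n_frames, n_atoms, 3); ``energies`` holds the
    potential energy (pair + restraints) of each saved frame.
    """

    frames: np.ndarray
    energies: np.ndarray
    lam: float
    settings: SamplerSettings
    specs: tuple
    final_positions: np.ndarray = None
    final_velocities: np.ndarray = None
    retried: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def potential_energy(system: ParticleSystem, model: PotentialModel,
                     spec, restraints: Sequence = ()) -> float:
    """Total potential energy at an alchemical state, kcal/mol."""
    nl = build_neighbor_list(system, model.r_cut)
    anl = apply_alchemy(nl, system, spec)
    e = energy(model, anl)
    for r in restraints:
        e += restraint_energy(r, system)
    return e


def _total_forces(system, model, spec, restraints):
    nl = build_neighbor_list(system, model.r_cut)
    anl = apply_alchemy(nl, system, spec)
    f = forces(model, system, anl)
    for r in restraints:
        f += restraint_forces(r, system)
    if not np.all(np.isfinite(f)):
        bad = np.unique(np.where(~np.isfinite(f))[0])
        raise InstabilityError(
            f"non-finite force on atoms {bad.tolist()}", atoms=bad.tolist()
        )
    return f


def maxwell_velocities(system: ParticleSystem, thermo: ThermoState,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities, A/ps."""
    kt_akma = thermo.kt * KCAL_MOL_TO_AKMA
    sigma = np.sqrt(kt_akma / system.masses)[:, None]
    return sigma * rng.standard_normal(system.positions.shape)


def langevin_step(system: ParticleSystem, model: PotentialModel, spec,
                  settings: SamplerSettings, velocities: np.ndarray,
                  rng: np.random.Generator, restraints: Sequence = (),
                  cached_forces: np.ndarray | None = None):
    """One BAOAB Langevin update; returns (system, velocities, forces).

    Deterministic given the generator state.  ``cached_forces`` lets the
    caller reuse the forces from the end of the previous step (BAOAB needs
    one evaluation per step).
    """
    dt = settings.timestep
    m = system.masses[:, None]
    kt_akma = settings.thermo.kt * KCAL_MOL_TO_AKMA
    f = cached_forces if cached_forces is not None else _total_forces(
        system, model, spec, restraints)

    v = velocities + 0.5 * dt * f * KCAL_MOL_TO_AKMA / m           # B
    x = system.positions + 0.5 * dt * v                            # A
    c1 = np.exp(-settings.friction * dt)                           # O
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    v = c1 * v + c2 * np.sqrt(kt_akma / m) * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v                                           # A
    new_system = system.with_positions(x)
    f = _total_forces(new_system, model, spec, restraints)
    v = v + 0.5 * dt * f * KCAL_MOL_TO_AKMA / m                    # B
    return new_system, v, f


def _run_once(system, model, spec, settings, restraints, velocities):
    rng = np.random.default_rng(settings.seed)
    v = velocities if velocities is not None else maxwell_velocities(
        system, settings.thermo, rng)
    n_frames = settings.n_steps // settings.save_interval
    frames = np.empty((n_frames, system.n_atoms, 3))
    energies = np.empty(n_frames)
    f = _total_forces(system, model, spec, restraints)
    k = 0
    for step in range(1, settings.n_steps + 1):
        system, v, f = langevin_step(system, model, spec, settings, v, rng,
                                     restraints, cached_forces=f)
        if step % settings.save_interval == 0:
            e = potential_energy(system, model, spec, restraints)
            if not np.isfinite(e):
                raise InstabilityError("non-finite potential energy")
            frames[k] = system.positions
            energies[k] = e
            k += 1
    lam = spec.lam if isinstance(spec, AlchemicalSpec) else spec[0].lam
    return Trajectory(
        frames=frames[:k], energies=energies[:k], lam=lam,
        settings=settings, specs=(spec,) if isinstance(spec, AlchemicalSpec)
        else tuple(spec),
        final_positions=system.positions.copy(),
        final_velocities=v.copy(),
    )


def run_window(system: ParticleSystem, model: PotentialModel, spec,
               settings: SamplerSettings, restraints: Sequence = (),
               velocities: np.ndarray | None = None) -> Trajectory:
    """Sample one lambda-window.

    On an :class:`InstabilityError` the window is retried once from the
    same start with the timestep halved; step counts and saving interval
    are doubled so the physical length and the saved time grid are
    unchanged.  A second failure propagates.
    """
    try:
        return _run_once(system, model, spec, settings, restraints,
                         velocities)
    except InstabilityError:
        retry = replace(settings,
                        timestep=0.5 * settings.timestep,
                        n_steps=2 * settings.n_steps,
                        save_interval=2 * settings.save_interval)
        traj = _run_once(system, model, spec, retry, restraints, velocities)
        traj.retried = True
        return traj


def mc_barostat_move(system: ParticleSystem, model: PotentialModel, spec,
                     thermo: ThermoState, rng: np.random.Generator,
                     restraints: Sequence = (), max_dlnv: float = 0.02):
    """Optional isotropic Monte Carlo volume move (NPT support).

    Proposes V -> V * exp(delta), rescales coordinates isotropically and
    accepts with the standard NPT criterion.  Returns (system, accepted).
    Off by default everywhere; provided for completeness.
    """
    if thermo.pressure is None:
        raise ValueError("barostat requires a pressure in the thermo state")
    # atm * A^3 -> kcal/mol
    p_kcal = thermo.pressure * 1.4584e-5
    v0 = float(np.prod(system.box))
    e0 = potential_energy(system, model, spec, restraints)
    delta = rng.uniform(-max_dlnv, max_dlnv)
    scale = np.exp(delta / 3.0)
    trial = ParticleSystem(
        positions=system.positions * scale,
        species=system.species, masses=system.masses,
        box=system.box * scale, solute_indices=system.solute_indices,
    )
    try:
        e1 = potential_energy(trial, model, spec, restraints)
    except ValueError:
        return system, False
    v1 = v0 * np.exp(delta)
    n = system.n_atoms
    arg = -thermo.beta * (e1 - e0 + p_kcal * (v1 - v0)) \
        + (n + 1) * np.log(v1 / v0)
    if np.log(rng.uniform()) < arg:
        return trial, True
    return system, False
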