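"""Potential backends operating strictly on the neighbor list.

The backend contract is the whole point of the method: a potential may see
atoms *only* through neighbor-list entries and their (possibly modified)
distances.  Any backend honouring the contract inherits masking and
lambda-shifting for free, regardless of its internal architecture.  Here a
smoothly-switched Lennard-Jones pair potential stands in for a trained
neural network potential; a switched harmonic pair model is provided for
analytically solvable test systems, and flat-bottom restraints keep weakly
coupled atoms near their sites.

All pair terms vanish identically at d >= r_cut (cubic switch), so
dropping entries whose shifted distance reaches the cutoff is exact.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .neighborlist import AlchemicalNeighborList
from .system import ParticleSystem, minimum_image

__all__ = [
    "PotentialModel",
    "ToyPairPotential",
    "HarmonicPairPotential",
    "CompositePotential",
    "FlatBottomRestraint",
    "energy",
    "forces",
    "restraint_energy",
    "restraint_forces",
]


def _switch(d: np.ndarray, r_on: float, r_cut: float):
    """C1 cubic switching function and its derivative.

    1 below ``r_on``, 0 above ``r_cut``, with zero slope at both edges.
    """
    d = np.asarray(d, dtype=float)
    t = np.clip((d - r_on) / (r_cut - r_on), 0.0, 1.0)
    s = 1.0 - t * t * (3.0 - 2.0 * t)
    ds = -6.0 * t * (1.0 - t) / (r_cut - r_on)
    ds = np.where((d > r_on) & (d < r_cut), ds, 0.0)
    return s, ds


class PotentialModel(abc.ABC):
    """Contract: energy as a function of neighbor-list entries only.

    Implementations provide vectorised per-pair energies and derivatives
    given the endpoint species and the (modified) pair distance.  They must
    be continuous with energy -> 0 as d -> r_cut.
    """

    r_cut: float

    @abc.abstractmethod
    def pair_energy_and_derivative(self, species_i, species_j, d):
        """Per-pair energy u(d) (kcal/mol) and du/dd (kcal/mol/A)."""

    def pair_energy(self, species_i, species_j, d):
        return self.pair_energy_and_derivative(species_i, species_j, d)[0]


@dataclass
class ToyPairPotential(PotentialModel):
    """Switched Lennard-Jones pair potential, the stand-in for an NNP.

    Per-species well depths ``eps`` (kcal/mol) and sizes ``sigma`` (A) are
    combined by Lorentz-Berthelot rules; the 12-6 term is multiplied by a
    cubic switch from ``switch_start * r_cut`` to ``r_cut``.  Species with
    eps = 0 are non-interacting ghosts.  Unknown species raise.
    """

    eps: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    r_cut: float = 5.0
    switch_start: float = 0.8

    def _params(self, species_i, species_j):
        try:
            e_i = np.array([self.eps[s] for s in species_i])
            e_j = np.array([self.eps[s] for s in species_j])
            s_i = np.array([self.sigma[s] for s in species_i])
            s_j = np.array([self.sigma[s] for s in species_j])
        except KeyError as exc:
            raise KeyError(f"species without parameters: {exc}") from exc
        return np.sqrt(e_i * e_j), 0.5 * (s_i + s_j)

    def pair_energy_and_derivative(self, species_i, species_j, d):
        d = np.asarray(d, dtype=float)
        eps, sig = self._params(species_i, species_j)
        r_on = self.switch_start * self.r_cut
        inv = sig / np.maximum(d, 1e-12)
        i6 = inv ** 6
        lj = 4.0 * eps * (i6 * i6 - i6)
        dlj = 4.0 * eps * (-12.0 * i6 * i6 + 6.0 * i6) / np.maximum(d, 1e-12)
        s, ds = _switch(d, r_on, self.r_cut)
        u = np.where(d < self.r_cut, lj * s, 0.0)
        du = np.where(d < self.r_cut, dlj * s + lj * ds, 0.0)
        return u, du


@dataclass
class HarmonicPairPotential(PotentialModel):
    """Switched harmonic springs between specific species pairs.

    ``params`` maps a frozenset of two species labels to ``(k, d0)`` with
    k in kcal/mol/A^2 and d0 in A.  Pairs without parameters contribute
    zero.  The spring is multiplied by the same cubic switch as the toy
    potential so it, too, vanishes at the cutoff; test systems keep their
    wells far inside the switching region, where the model is exactly
    0.5 k (d - d0)^2.
    """

    params: dict = field(default_factory=dict)
    r_cut: float = 5.0
    switch_start: float = 0.8

    def pair_energy_and_derivative(self, species_i, species_j, d):
        d = np.asarray(d, dtype=float)
        k = np.zeros_like(d)
        d0 = np.zeros_like(d)
        for n, (a, b) in enumerate(zip(species_i, species_j)):
            p = self.params.get(frozenset((a, b)))
            if p is not None:
                k[n], d0[n] = p
        r_on = self.switch_start * self.r_cut
        harm = 0.5 * k * (d - d0) ** 2
        dharm = k * (d - d0)
        s, ds = _switch(d, r_on, self.r_cut)
        u = np.where(d < self.r_cut, harm * s, 0.0)
        du = np.where(d < self.r_cut, dharm * s + harm * ds, 0.0)
        return u, du


@dataclass
class CompositePotential(PotentialModel):
    """Sum of component models sharing one cutoff."""

    components: tuple = ()

    def __post_init__(self):
        cuts = {m.r_cut for m in self.components}
        if len(cuts) != 1:
            raise ValueError("all components must share r_cut")
        self.r_cut = cuts.pop()

    def pair_energy_and_derivative(self, species_i, species_j, d):
        u = np.zeros(len(np.atleast_1d(d)))
        du = np.zeros_like(u)
        for m in self.components:
            ui, dui = m.pair_energy_and_derivative(species_i, species_j, d)
            u = u + ui
            du = du + dui
        return u, du


def energy(model: PotentialModel, anl: AlchemicalNeighborList) -> float:
    """Total pair energy of a (possibly alchemically modified) list, kcal/mol.

    Evaluated at the *modified* distances — this is the entire coupling of
    the alchemistry to the potential.
    """
    if len(anl) == 0:
        return 0.0
    u, _ = model.pair_energy_and_derivative(
        anl.species_i, anl.species_j, anl.d_mod
    )
    return float(np.sum(u))


def forces(model: PotentialModel, system: ParticleSystem,
           anl: AlchemicalNeighborList) -> np.ndarray:
    """Per-atom forces -dE/dr, kcal/mol/A, including the shift chain rule.

    The modified distance depends on coordinates only through the true
    distance, so the force on the real separation is
    ``-u'(d_mod) * chain * unit_vector`` accumulated antisymmetrically.
    Overlapping atoms (d = 0 on a listed pair) are an error.
    """
    f = np.zeros_like(system.positions)
    if len(anl) == 0:
        return f
    if np.any(anl.d < 1e-8):
        bad = np.argmin(anl.d)
        raise ValueError(
            f"overlapping atoms {int(anl.i[bad])},{int(anl.j[bad])} (d~0)"
        )
    _, du = model.pair_energy_and_derivative(
        system.species[anl.i], system.species[anl.j], anl.d_mod
    )
    # dE/dr_i = u'(d') * chain * disp/d  with disp = r_i - r_j
    g = (du * anl.chain / anl.d)[:, None] * anl.disp
    np.subtract.at(f, anl.i, g)
    np.add.at(f, anl.j, g)
    return f


@dataclass
class FlatBottomRestraint:
    """Zero inside a sphere of radius ``r0``, harmonic outside.

    Anchors an atom either to a fixed point (``anchor_point``, A) or to
    another atom (``anchor_atom``).  Energy 0.5 kf (r - r0)^2 for r > r0,
    C1-continuous at the boundary.
    """

    atom: int
    r0: float
    kf: float
    anchor_point: np.ndarray | None = None
    anchor_atom: int | None = None

    def __post_init__(self):
        if (self.anchor_point is None) == (self.anchor_atom is None):
            raise ValueError("exactly one of anchor_point/anchor_atom required")
        if self.anchor_point is not None:
            self.anchor_point = np.asarray(self.anchor_point, dtype=float)
        if self.r0 < 0 or self.kf < 0:
            raise ValueError("r0 and kf must be >= 0")

    def _delta(self, system: ParticleSystem):
        pos = system.positions[self.atom]
        ref = (self.anchor_point if self.anchor_point is not None
               else system.positions[self.anchor_atom])
        return minimum_image(pos - ref, system.box)


def restraint_energy(restraint: FlatBottomRestraint,
                     system: ParticleSystem) -> float:
    """Flat-bottom well energy, kcal/mol."""
    delta = restraint._delta(system)
    r = float(np.linalg.norm(delta))
    if r <= restraint.r0:
        return 0.0
    return 0.5 * restraint.kf * (r - restraint.r0) ** 2


def restraint_forces(restraint: FlatBottomRestraint,
                     system: ParticleSystem) -> np.ndarray:
    """Forces of one flat-bottom restraint on all atoms."""
    f = np.zeros_like(system.positions)
    delta = restraint._delta(system)
    r = float(np.linalg.norm(delta))
    if r <= restraint.r0 or r == 0.0:
        return f
    g = restraint.kf * (r - restraint.r0) / r * delta
    f[restraint.atom] -= g
    if restraint.anchor_atom is not None:
        f[restraint.anchor_atom] += g
    return f
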