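"""Particle systems and periodic geometry.

A :class:`ParticleSystem` is the in-memory container every other module
consumes: coordinates, species labels, masses, an orthorhombic periodic
box, and the solute/solvent index partition that decides which atom pairs
an alchemical transformation is allowed to touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB_KCAL_MOL_K

__all__ = [
    "ParticleSystem",
    "ThermoState",
    "minimum_image_displacement",
    "minimum_image",
]


@dataclass
class ParticleSystem:
    """A set of point particles in an orthorhombic periodic box.

    Parameters
    ----------
    positions
        ``(n, 3)`` Cartesian coordinates, A.
    species
        Length-``n`` sequence of chemical labels (e.g. ``"W"``, ``"S"``).
    masses
        Length-``n`` masses, amu.
    box
        Three orthorhombic box lengths, A.
    solute_indices
        Indices of the solute atoms; the complement is the solvent.
    """

    positions: np.ndarray
    species: np.ndarray
    masses: np.ndarray
    box: np.ndarray
    solute_indices: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype=object).reshape(-1)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.solute_indices = frozenset(int(i) for i in self.solute_indices)
        n = self.n_atoms
        if len(self.species) != n or len(self.masses) != n:
            raise ValueError("positions, species and masses must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.box > 0):
            raise ValueError("every box length must be > 0")
        if self.solute_indices and (
            min(self.solute_indices) < 0 or max(self.solute_indices) >= n
        ):
            raise ValueError("solute indices out of range")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def solvent_indices(self) -> frozenset:
        return frozenset(range(self.n_atoms)) - self.solute_indices

    def is_solute_mask(self) -> np.ndarray:
        """Boolean per-atom mask, True for solute atoms."""
        mask = np.zeros(self.n_atoms, dtype=bool)
        if self.solute_indices:
            mask[sorted(self.solute_indices)] = True
        return mask

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        """Copy of the system with replaced coordinates."""
        return replace(self, positions=np.array(positions, dtype=float))

    def subset(self, indices) -> "ParticleSystem":
        """Sub-system containing only ``indices`` (order preserved).

        Solute membership is carried over and re-indexed.
        """
        idx = np.asarray(sorted(int(i) for i in indices), dtype=int)
        remap = {int(old): new for new, old in enumerate(idx)}
        solute = frozenset(
            remap[i] for i in self.solute_indices if i in remap
        )
        return ParticleSystem(
            positions=self.positions[idx].copy(),
            species=self.species[idx].copy(),
            masses=self.masses[idx].copy(),
            box=self.box.copy(),
            solute_indices=solute,
        )


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state point.

    ``beta`` is derived, 1/(k_B T) in mol/kcal.  ``pressure`` (atm) is only
    consulted by the optional Monte Carlo barostat.
    """

    temperature: float
    pressure: float | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL_MOL_K * self.temperature)

    @property
    def kt(self) -> float:
        """k_B T, kcal/mol."""
        return KB_KCAL_MOL_K * self.temperature


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap raw displacement(s) ``delta`` into the minimum-image convention.

    Works on a single 3-vector or an ``(m, 3)`` array.  Each component of
    the result has magnitude <= box/2.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.rint(delta / box)


def minimum_image_displacement(pos_i, pos_j, box):
    """Minimum-image displacement ``pos_i - pos_j`` and its length.

    Returns
    -------
    (displacement, distance)
        ``displacement`` is the 3-vector pointing from j to i under the
        minimum-image convention; ``distance`` its Euclidean norm.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(pos_i)) and np.all(np.isfinite(pos_j))):
        raise ValueError("non-finite coordinates")
    if not np.all(box > 0):
        raise ValueError("every box length must be > 0")
    disp = minimum_image(pos_i - pos_j, box)
    return disp, float(np.linalg.norm(disp))
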