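"""Neighbor-list construction, masking, and lambda-dependent distance shifting.

The neighbor list — the set of atom pairs with interatomic distance below a
cutoff ``r_cut`` — is the first step of every cutoff-based potential, which
makes it a universal hook for alchemistry:

* **Masking** removes every list entry involving an atom, which for any
  potential that sees atoms only through the list is exactly equivalent to
  deleting the atom.
* **Distance shifting** replaces the true pair distance ``d`` of selected
  entries by a lambda-dependent modified distance ``d'(lam)`` that equals
  ``d`` at lam=0 and exceeds ``r_cut`` at lam=1, fading the interaction out
  as if the atom retreated along a fictitious fourth dimension.

Four shifting schemes are provided, two linear and two genuinely 4D, each
in a "beyond the cutoff" and a "to the cutoff" variant:

=======  =======================================================
scheme   modified distance d'(lam)
=======  =======================================================
1        d + lam * r_cut
2        d + lam * max(0, r_cut - d) + lam * eps
3        sqrt(d**2 + (lam * r_cut)**2)
4        sqrt(d**2 + lam * max(r_cut**2 - d**2, 0)) + lam * eps
=======  =======================================================

The guard ``eps`` keeps schemes 2 and 4 strictly past the cutoff at lam=1
despite rounding.  It is scaled by lam so that lam=0 is an *exact* identity
— the method's two stated end-state properties (identity at lam=0, empty
modified list at lam=1) then hold simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .system import ParticleSystem, minimum_image

__all__ = [
    "NeighborList",
    "AlchemicalSpec",
    "AlchemicalNeighborList",
    "build_neighbor_list",
    "mask_atoms",
    "shift_distance",
    "shift_chain_factor",
    "apply_alchemy",
    "solute_solvent_selector",
    "single_atom_selector",
]

SCHEMES = (1, 2, 3, 4)


@lru_cache(maxsize=8)
def _triu_indices(n: int):
    return np.triu_indices(n, k=1)


@dataclass
class NeighborList:
    """Half (unordered-pair) cutoff neighbor list.

    Entries are stored column-wise: ``i``/``j`` atom indices (i < j),
    distances ``d`` (A) and minimum-image displacements ``disp``
    (``pos[i] - pos[j]``, shape ``(m, 3)``).
    """

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    disp: np.ndarray
    r_cut: float

    def __len__(self) -> int:
        return len(self.d)

    def pairs(self) -> set:
        """Set of unordered index pairs, for comparisons in tests."""
        return {(int(a), int(b)) for a, b in zip(self.i, self.j)}


def build_neighbor_list(system: ParticleSystem, r_cut: float) -> NeighborList:
    """All unordered pairs with minimum-image distance < ``r_cut``.

    Requires every box length > 2 r_cut so the minimum image is unambiguous
    (each atom sees at most one periodic copy of any other within the
    cutoff).
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be > 0")
    if np.any(system.box <= 2.0 * r_cut):
        raise ValueError(
            f"box {system.box} too small for r_cut={r_cut}: "
            "every box length must exceed 2*r_cut"
        )
    n = system.n_atoms
    iu, ju = _triu_indices(n)
    disp = minimum_image(system.positions[iu] - system.positions[ju], system.box)
    d2 = np.einsum("ij,ij->i", disp, disp)
    keep = d2 < r_cut * r_cut
    return NeighborList(
        i=iu[keep].copy(),
        j=ju[keep].copy(),
        d=np.sqrt(d2[keep]),
        disp=disp[keep].copy(),
        r_cut=float(r_cut),
    )


def mask_atoms(nl: NeighborList, masked) -> NeighborList:
    """Remove every entry with an endpoint in ``masked``.

    Masking an atom this way hides it completely from any potential that
    consumes the list; it is exactly equivalent to deleting the atom.
    """
    masked = frozenset(int(a) for a in masked)
    if not masked:
        return nl
    lut = np.zeros(max(int(nl.i.max(initial=-1)), int(nl.j.max(initial=-1))) + 2,
                   dtype=bool)
    for a in masked:
        if a < 0:
            raise IndexError(f"masked atom index {a} invalid")
        if a < len(lut):
            lut[a] = True
    keep = ~(lut[nl.i] | lut[nl.j]) if len(nl) else np.zeros(0, dtype=bool)
    return NeighborList(
        i=nl.i[keep], j=nl.j[keep], d=nl.d[keep], disp=nl.disp[keep],
        r_cut=nl.r_cut,
    )


@dataclass
class AlchemicalSpec:
    """One lambda-dependent modification of a neighbor list.

    Parameters
    ----------
    scheme
        Shifting scheme, 1-4 (see module docstring).
    lam
        Coupling parameter in [0, 1]; 0 = fully coupled, 1 = decoupled.
    epsilon
        Guard distance (A) keeping schemes 2/4 strictly past the cutoff
        at lam=1.
    pair_selector
        Vectorised rule ``(i, j, system) -> bool array`` marking the pairs
        whose distance is modified.  Default: solute-solvent cross pairs.
    masked_atoms
        Atoms removed from the list entirely (at every lambda).
    masked_pairs
        Individual unordered pairs removed entirely; used by dual-topology
        transformations to hide the two variant atoms from each other.
    """

    scheme: int = 2
    lam: float = 0.0
    epsilon: float = 1e-4
    pair_selector: Callable | None = None
    masked_atoms: frozenset = field(default_factory=frozenset)
    masked_pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        self.masked_atoms = frozenset(int(a) for a in self.masked_atoms)
        self.masked_pairs = frozenset(
            (min(int(a), int(b)), max(int(a), int(b)))
            for a, b in self.masked_pairs
        )

    def selector(self) -> Callable:
        return self.pair_selector or solute_solvent_selector


def solute_solvent_selector(i, j, system: ParticleSystem):
    """Modified iff exactly one endpoint is a solute atom (cross pairs).

    This is the decoupling rule for absolute solvation free energies:
    intrasolute and solvent-solvent interactions stay untouched.
    """
    sol = system.is_solute_mask()
    return sol[i] ^ sol[j]


def single_atom_selector(atom: int) -> Callable:
    """Selector modifying every pair involving one atom (per-atom decoupling).

    Used by relative (dual-topology) transformations where a single variant
    atom appears or disappears.
    """
    atom = int(atom)

    def _select(i, j, system):
        return (np.asarray(i) == atom) | (np.asarray(j) == atom)

    return _select


def _shift_arrays(d: np.ndarray, r_cut: float, scheme: int, lam: float,
                  eps: float):
    """Vectorised modified distance and its d-derivative (chain factor)."""
    d = np.asarray(d, dtype=float)
    if scheme == 1:
        dp = d + lam * r_cut
        chain = np.ones_like(d)
    elif scheme == 2:
        dp = d + lam * np.maximum(0.0, r_cut - d) + lam * eps
        chain = np.full_like(d, 1.0 - lam)
    elif scheme == 3:
        dp = np.sqrt(d * d + (lam * r_cut) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            chain = np.where(dp > 0, d / np.where(dp > 0, dp, 1.0), 1.0)
    else:  # scheme 4
        root = np.sqrt(d * d + lam * np.maximum(r_cut * r_cut - d * d, 0.0))
        dp = root + lam * eps
        with np.errstate(invalid="ignore", divide="ignore"):
            chain = np.where(root > 0,
                             d * (1.0 - lam) / np.where(root > 0, root, 1.0),
                             0.0 if lam > 0 else 1.0)
    return dp, chain


def shift_distance(d, r_cut: float, spec: AlchemicalSpec):
    """Modified distance d'(lam) for a pair currently at distance ``d``.

    Only listed pairs (0 <= d < r_cut) may be shifted; a distance at or
    beyond the cutoff is a usage error.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0) or np.any(arr >= r_cut):
        raise ValueError("shift_distance requires 0 <= d < r_cut")
    dp, _ = _shift_arrays(arr, r_cut, spec.scheme, spec.lam, spec.epsilon)
    return float(dp) if np.isscalar(d) else dp


def shift_chain_factor(d, r_cut: float, spec: AlchemicalSpec):
    """Derivative d(d')/d(d) of the shift at true distance ``d``.

    Needed by the force chain rule: the fictitious-dimension offset carries
    no force component of its own, so the force along the real separation
    is the pair derivative at d' times this factor.  At d=0 the schemes
    with a vanishing radial derivative (3 and 4 for lam>0) return the
    limiting value 0 rather than raising.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0) or np.any(arr >= r_cut):
        raise ValueError("shift_chain_factor requires 0 <= d < r_cut")
    _, ch = _shift_arrays(arr, r_cut, spec.scheme, spec.lam, spec.epsilon)
    return float(ch) if np.isscalar(d) else ch


@dataclass
class AlchemicalNeighborList:
    """Neighbor list after masking and lambda-dependent shifting.

    ``d_mod`` holds the per-entry modified distance, ``chain`` the
    derivative of the modified distance with respect to the true one
    (1 for unmodified pairs).  Entries whose modified distance reached the
    cutoff have been dropped — for a potential that vanishes at the cutoff
    this is exact, and it reproduces the decoupled end state in which the
    shifted pairs are simply absent from the list.
    """

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    d_mod: np.ndarray
    disp: np.ndarray
    chain: np.ndarray
    species_i: np.ndarray
    species_j: np.ndarray
    r_cut: float
    specs: tuple

    def __len__(self) -> int:
        return len(self.d)

    def pairs(self) -> set:
        return {(int(a), int(b)) for a, b in zip(self.i, self.j)}


def apply_alchemy(nl: NeighborList, system: ParticleSystem,
                  spec: AlchemicalSpec | Sequence[AlchemicalSpec]
                  ) -> AlchemicalNeighborList:
    """Apply masking and distance shifting to a neighbor list.

    ``spec`` may be a single :class:`AlchemicalSpec` or a sequence of specs
    with *disjoint* pair selectors (each with its own lambda), as used by
    dual-topology transformations.  Masked atoms and masked pairs from all
    specs are removed first; each selected pair is then shifted by the spec
    that claims it; unclaimed pairs pass through with chain factor 1;
    entries whose modified distance is >= r_cut are dropped.
    """
    specs = (spec,) if isinstance(spec, AlchemicalSpec) else tuple(spec)
    n = system.n_atoms
    for sp in specs:
        if sp.masked_atoms and max(sp.masked_atoms) >= n:
            raise IndexError("masked atom index out of range")

    masked = frozenset().union(*(sp.masked_atoms for sp in specs))
    work = mask_atoms(nl, masked)

    i, j, d, disp = work.i, work.j, work.d, work.disp
    m = len(d)
    keep = np.ones(m, dtype=bool)
    masked_pairs = frozenset().union(*(sp.masked_pairs for sp in specs))
    if masked_pairs and m:
        pair_keys = [(int(a), int(b)) for a, b in zip(i, j)]
        keep &= np.array([p not in masked_pairs for p in pair_keys])
    i, j, d, disp = i[keep], j[keep], d[keep], disp[keep]
    m = len(d)

    d_mod = d.copy()
    chain = np.ones(m)
    claimed = np.zeros(m, dtype=bool)
    for sp in specs:
        sel = np.asarray(sp.selector()(i, j, system), dtype=bool)
        if sel.shape != (m,):
            raise ValueError("pair selector returned wrong shape")
        sel = sel & ~claimed
        claimed |= sel
        if not sel.any():
            continue
        dp, ch = _shift_arrays(d[sel], nl.r_cut, sp.scheme, sp.lam, sp.epsilon)
        d_mod[sel] = dp
        chain[sel] = ch

    within = d_mod < nl.r_cut
    i, j = i[within], j[within]
    return AlchemicalNeighborList(
        i=i, j=j, d=d[within], d_mod=d_mod[within],
        disp=disp[within], chain=chain[within],
        species_i=system.species[i], species_j=system.species[j],
        r_cut=nl.r_cut, specs=specs,
    )
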