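"""Seeded generation of toy systems.

Everything the test-suite and the worked examples run on is generated
here, deterministically from a seed: a relaxed box of toy solvent
particles, a compact four-particle toy solute, and a "tautomer-like" pair
of solutes differing only in the site of a single variant particle.  The
generator emulates the *structure* of a solvation study — a solute
embedded in a periodic solvent bath, a gas-phase copy, restraints holding
weakly coupled atoms near their sites — not the chemistry of water.

Default species (Lennard-Jones, Lorentz-Berthelot):

=========  ===========  ==========  =========
species    eps kcal/mol  sigma A    mass amu
=========  ===========  ==========  =========
W solvent  0.20          3.00       18.0
S solute   0.30          3.20       16.0
V variant  0.25          3.00       10.0
=========  ===========  ==========  =========

All randomness uses numpy's PCG64 generator, so identical recipe + seed
reproduce systems bit-for-bit across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .neighborlist import build_neighbor_list
from .potentials import FlatBottomRestraint, ToyPairPotential
from .system import ParticleSystem, minimum_image

__all__ = [
    "FixtureRecipe",
    "default_model",
    "make_toy_solvent_box",
    "make_toy_solute_pair",
    "embed_solute",
    "make_cycle_fixture",
    "ToySolutePair",
    "CycleFixture",
]

SOLVENT = {"eps": 0.20, "sigma": 3.00, "mass": 18.0}
SOLUTE = {"eps": 0.30, "sigma": 3.20, "mass": 16.0}
VARIANT = {"eps": 0.25, "sigma": 3.00, "mass": 10.0}

#: Core solute geometry (local frame, A): a triangle at Lennard-Jones
#: contact, with the variant site above its centroid.
CORE_SITES = np.array([
    [1.60, -0.92, 0.0],
    [-1.60, -0.92, 0.0],
    [0.0, 1.85, 0.0],
])
VARIANT_SITE_1 = np.array([0.0, 0.0, 1.9])
CORE_RESTRAINT = {"r0": 0.75, "kf": 20.0}
VARIANT_RESTRAINT = {"r0": 1.0, "kf": 10.0}


@dataclass(frozen=True)
class FixtureRecipe:
    """Recipe for the default toy cycle system."""

    name: str = "toy-cycle"
    n_solvent: int = 50
    box_length: float = 12.0
    gas_box_length: float = 50.0
    site_separation: float = 1.5
    seed: int = 0
    r_cut: float = 5.0


def default_model(r_cut: float = 5.0) -> ToyPairPotential:
    """The toy Lennard-Jones model with the default species table."""
    return ToyPairPotential(
        eps={"W": SOLVENT["eps"], "S": SOLUTE["eps"], "V": VARIANT["eps"]},
        sigma={"W": SOLVENT["sigma"], "S": SOLUTE["sigma"],
               "V": VARIANT["sigma"]},
        r_cut=r_cut,
    )


def _steepest_descent(positions, box, model, species, n_iter=50,
                      max_step=0.1, exclude_points=None, exclude_radius=0.0):
    """Crude energy relaxation; keeps points out of exclusion spheres."""
    from .potentials import forces as _forces
    from .neighborlist import apply_alchemy, AlchemicalSpec

    sys_ = ParticleSystem(positions=positions, species=species,
                          masses=np.ones(len(positions)), box=box)
    for _ in range(n_iter):
        nl = build_neighbor_list(sys_, model.r_cut)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec(lam=0.0))
        f = _forces(model, sys_, anl)
        norm = np.linalg.norm(f, axis=1).max()
        if norm < 1e-6:
            break
        step = f * (max_step / max(norm, 1e-12))
        pos = sys_.positions + step
        if exclude_points is not None and exclude_radius > 0:
            pos = _push_out(pos, box, exclude_points, exclude_radius)
        sys_ = sys_.with_positions(pos)
    return sys_.positions


def _push_out(pos, box, points, radius):
    pos = pos.copy()
    for p in points:
        delta = minimum_image(pos - p, box)
        r = np.linalg.norm(delta, axis=1)
        bad = r < radius
        if bad.any():
            scale = radius / np.maximum(r[bad], 1e-9)
            pos[bad] = p + delta[bad] * scale[:, None]
    return pos


def make_toy_solvent_box(n: int, box_length: float, seed: int,
                         min_dist_frac: float = 0.85,
                         exclude_points=None,
                         exclude_radius: float = 0.0,
                         relax: bool = True) -> ParticleSystem:
    """Random, relaxed box of ``n`` toy solvent particles.

    Particles are placed by rejection sampling (minimum-image pair
    distance >= ``min_dist_frac * sigma``, optionally outside exclusion
    spheres around ``exclude_points``), then relaxed by a short steepest
    descent.  Deterministic per seed; an unattainable density raises.
    """
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_length))
    sigma = SOLVENT["sigma"]
    min_dist = min_dist_frac * sigma
    placed = np.empty((0, 3))
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 5000 + 200 * n:
            raise ValueError(
                f"cannot place {n} particles at min distance {min_dist:.2f} "
                f"in a {box_length} A box (density unattainable)"
            )
        trial = rng.uniform(0.0, box_length, size=3)
        if exclude_points is not None and exclude_radius > 0:
            deltas = minimum_image(trial - np.asarray(exclude_points), box)
            if np.any(np.linalg.norm(deltas, axis=1) < exclude_radius):
                continue
        if len(placed):
            deltas = minimum_image(trial - placed, box)
            if np.min(np.linalg.norm(deltas, axis=1)) < min_dist:
                continue
        placed = np.vstack([placed, trial])

    species = np.array(["W"] * n, dtype=object)
    if n > 1 and relax:
        placed = _steepest_descent(
            placed, box, default_model(), species,
            exclude_points=exclude_points, exclude_radius=exclude_radius,
        )
    sys_ = ParticleSystem(
        positions=placed, species=species,
        masses=np.full(n, SOLVENT["mass"]), box=box,
    )
    if n > 1:
        nl = build_neighbor_list(sys_, 5.0)
        if len(nl) and nl.d.min() < min_dist - 1e-9:
            raise AssertionError("relaxation violated the minimum distance")
    return sys_


class ToySolutePair(NamedTuple):
    """Two gas-phase solutes differing at one variant site, plus restraints.

    ``t1``/``t2`` are full :class:`ParticleSystem` objects (variant atom
    last); restraints anchor every atom to its site and are *identical* in
    both systems except for the variant anchor, which sits at site 1 or 2.
    """

    t1: ParticleSystem
    t2: ParticleSystem
    variant_index: int
    restraints_t1: tuple
    restraints_t2: tuple
    site1: np.ndarray
    site2: np.ndarray


def _solute_arrays(center, variant_site):
    positions = np.vstack([CORE_SITES + center, variant_site + center])
    species = np.array(["S", "S", "S", "V"], dtype=object)
    masses = np.array([SOLUTE["mass"]] * 3 + [VARIANT["mass"]])
    return positions, species, masses


def _solute_restraints(center, variant_site):
    rs = [
        FlatBottomRestraint(atom=k, anchor_point=CORE_SITES[k] + center,
                            **CORE_RESTRAINT)
        for k in range(3)
    ]
    rs.append(FlatBottomRestraint(atom=3, anchor_point=variant_site + center,
                                  **VARIANT_RESTRAINT))
    return tuple(rs)


def make_toy_solute_pair(recipe: FixtureRecipe = FixtureRecipe()
                         ) -> ToySolutePair:
    """Gas-phase tautomer-like pair: one particle at two alternative sites."""
    box = float(recipe.gas_box_length)
    center = np.full(3, box / 2.0)
    site1 = VARIANT_SITE_1.copy()
    site2 = VARIANT_SITE_1 + np.array([recipe.site_separation, 0.0, 0.0])

    systems = []
    restraints = []
    for site in (site1, site2):
        pos, spe, mas = _solute_arrays(center, site)
        systems.append(ParticleSystem(
            positions=pos, species=spe, masses=mas,
            box=np.full(3, box), solute_indices=frozenset(range(4)),
        ))
        restraints.append(_solute_restraints(center, site))
    return ToySolutePair(
        t1=systems[0], t2=systems[1], variant_index=3,
        restraints_t1=restraints[0], restraints_t2=restraints[1],
        site1=site1 + center, site2=site2 + center,
    )


def embed_solute(solute: ParticleSystem, solvent: ParticleSystem,
                 offset=None):
    """Place a solute into a solvent box: solute atoms first, solvent after.

    Solvent coordinates are carried over bit-exactly.  ``offset`` moves
    the solute (default: from its own box center to the solvent box
    center); returns the combined :class:`ParticleSystem`.
    """
    if offset is None:
        offset = solvent.box / 2.0 - solute.box / 2.0
    pos = np.vstack([solute.positions + offset, solvent.positions])
    return ParticleSystem(
        positions=pos,
        species=np.concatenate([solute.species, solvent.species]),
        masses=np.concatenate([solute.masses, solvent.masses]),
        box=solvent.box.copy(),
        solute_indices=frozenset(range(solute.n_atoms)),
    )


@dataclass
class CycleFixture:
    """Everything needed for one toy thermodynamic cycle.

    Gas and solvated versions of both end states, the potential model, and
    the restraint sets (anchors already in the right frame).
    """

    model: ToyPairPotential
    t1_gas: ParticleSystem
    t2_gas: ParticleSystem
    t1_solv: ParticleSystem
    t2_solv: ParticleSystem
    restraints_t1_gas: tuple
    restraints_t2_gas: tuple
    restraints_t1_solv: tuple
    restraints_t2_solv: tuple
    core_restraints_gas: tuple
    core_restraints_solv: tuple
    variant_index: int
    variant_restraint: dict = field(default_factory=lambda: dict(VARIANT_RESTRAINT))
    recipe: FixtureRecipe = field(default_factory=FixtureRecipe)


def make_cycle_fixture(seed: int, recipe: FixtureRecipe | None = None
                       ) -> CycleFixture:
    """Build the default toy cycle system for one seed.

    The solvent box is generated with exclusion spheres around the solute
    sites so the embedded system starts without overlaps; embedding keeps
    solvent coordinates bit-exact.
    """
    recipe = recipe or FixtureRecipe(seed=seed)
    pair = make_toy_solute_pair(recipe)
    gas_center = np.full(3, recipe.gas_box_length / 2.0)
    solv_center = np.full(3, recipe.box_length / 2.0)

    # Solute sites in the solvated frame (both variant sites excluded so
    # one solvent box serves T1 and T2).
    local_sites = np.vstack([
        CORE_SITES, pair.site1 - gas_center, pair.site2 - gas_center,
    ])
    solvent = make_toy_solvent_box(
        recipe.n_solvent, recipe.box_length, seed,
        exclude_points=local_sites + solv_center, exclude_radius=2.7,
    )

    t1_solv = embed_solute(pair.t1, solvent)
    t2_solv = embed_solute(pair.t2, solvent)

    shift = solv_center - gas_center

    def _shift_restraints(rs):
        return tuple(
            FlatBottomRestraint(atom=r.atom, r0=r.r0, kf=r.kf,
                                anchor_point=r.anchor_point + shift)
            for r in rs
        )

    r_t1_solv = _shift_restraints(pair.restraints_t1)
    r_t2_solv = _shift_restraints(pair.restraints_t2)
    return CycleFixture(
        model=default_model(recipe.r_cut),
        t1_gas=pair.t1, t2_gas=pair.t2,
        t1_solv=t1_solv, t2_solv=t2_solv,
        restraints_t1_gas=pair.restraints_t1,
        restraints_t2_gas=pair.restraints_t2,
        restraints_t1_solv=r_t1_solv,
        restraints_t2_solv=r_t2_solv,
        core_restraints_gas=pair.restraints_t1[:3],
        core_restraints_solv=r_t1_solv[:3],
        variant_index=pair.variant_index,
        recipe=recipe,
    )
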