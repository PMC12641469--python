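"""Potential backends: cutoff continuity, masking/decoupling equivalence,
force correctness through the shift chain rule, restraints."""

import numpy as np
import pytest

from nlfep.neighborlist import (SCHEMES, AlchemicalSpec, apply_alchemy,
                                build_neighbor_list)
from nlfep.potentials import (CompositePotential, FlatBottomRestraint,
                              HarmonicPairPotential, ToyPairPotential,
                              energy, forces, restraint_energy,
                              restraint_forces)
from nlfep.system import ParticleSystem

from conftest import random_system


def plain_energy(model, system, lam=0.0, scheme=2):
    nl = build_neighbor_list(system, model.r_cut)
    anl = apply_alchemy(nl, system, AlchemicalSpec(scheme=scheme, lam=lam))
    return energy(model, anl)


class TestEnergy:
    def test_empty_list_zero_energy(self, model):
        sys_ = ParticleSystem(positions=[[1, 1, 1]], species=["W"],
                              masses=[18.0], box=(20.0,) * 3)
        nl = build_neighbor_list(sys_, 5.0)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec())
        assert energy(model, anl) == 0.0

    def test_pair_at_cutoff_switched_to_zero(self, model):
        sys_ = ParticleSystem(
            positions=[[1, 1, 1], [1 + 5.0 - 1e-9, 1, 1]],
            species=["W", "W"], masses=[18.0] * 2, box=(20.0,) * 3,
        )
        assert abs(plain_energy(model, sys_)) < 1e-12

    def test_unknown_species_raises(self):
        model = ToyPairPotential(eps={"W": 0.2}, sigma={"W": 3.0}, r_cut=5.0)
        sys_ = ParticleSystem(positions=[[0, 0, 0], [3, 0, 0]],
                              species=["W", "Q"], masses=[18.0] * 2,
                              box=(20.0,) * 3)
        with pytest.raises(KeyError, match="Q"):
            plain_energy(model, sys_)

    def test_translation_invariance(self, model):
        sys_ = random_system(30, 12.0, seed=5)
        e0 = plain_energy(model, sys_)
        shifted = sys_.with_positions(sys_.positions + [3.7, -41.2, 8.9])
        assert plain_energy(model, shifted) == pytest.approx(e0, abs=1e-9)

    def test_relabeling_invariance(self, model):
        sys_ = random_system(25, 12.0, seed=6)
        e0 = plain_energy(model, sys_)
        perm = np.random.default_rng(0).permutation(25)
        relabeled = ParticleSystem(
            positions=sys_.positions[perm], species=sys_.species[perm],
            masses=sys_.masses[perm], box=sys_.box,
        )
        assert plain_energy(model, relabeled) == pytest.approx(e0, abs=1e-9)


class TestMaskingEquivalence:
    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_masking_equals_deletion(self, model, small_mixed_system, lam):
        sys_ = small_mixed_system
        masked_set = {2, 11, 17}
        nl = build_neighbor_list(sys_, model.r_cut)
        spec = AlchemicalSpec(scheme=2, lam=lam, masked_atoms=masked_set)
        e_masked = energy(model, apply_alchemy(nl, sys_, spec))

        keep = [a for a in range(sys_.n_atoms) if a not in masked_set]
        deleted = sys_.subset(keep)
        nl_d = build_neighbor_list(deleted, model.r_cut)
        e_deleted = energy(model, apply_alchemy(
            nl_d, deleted, AlchemicalSpec(scheme=2, lam=lam)))
        assert e_masked == pytest.approx(e_deleted, abs=1e-12)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_lambda_one_equals_separated_subsystems(self, model,
                                                    small_mixed_system,
                                                    scheme):
        sys_ = small_mixed_system
        nl = build_neighbor_list(sys_, model.r_cut)
        e_decoupled = energy(model, apply_alchemy(
            nl, sys_, AlchemicalSpec(scheme=scheme, lam=1.0)))

        solute = sys_.subset(sorted(sys_.solute_indices))
        solvent = sys_.subset(sorted(sys_.solvent_indices))
        e_parts = plain_energy(model, solute) + plain_energy(model, solvent)
        assert e_decoupled == pytest.approx(e_parts, abs=1e-10)


class TestForces:
    def num_forces(self, model, system, spec, h=1e-5):
        f = np.zeros_like(system.positions)
        for a in range(system.n_atoms):
            for k in range(3):
                for sgn, dst in ((1, -1.0), (-1, 1.0)):
                    pos = system.positions.copy()
                    pos[a, k] += sgn * h
                    nl = build_neighbor_list(system.with_positions(pos),
                                             model.r_cut)
                    anl = apply_alchemy(nl, system.with_positions(pos), spec)
                    f[a, k] += dst * energy(model, anl) / (2 * h)
        return f

    def test_lambda_zero_forces_are_plain_pair_forces(self, model,
                                                      small_mixed_system):
        sys_ = small_mixed_system
        nl = build_neighbor_list(sys_, model.r_cut)
        f0 = forces(model, sys_, apply_alchemy(nl, sys_, AlchemicalSpec(
            scheme=3, lam=0.0)))
        f1 = forces(model, sys_, apply_alchemy(nl, sys_, AlchemicalSpec(
            scheme=1, lam=0.0)))
        assert np.allclose(f0, f1, atol=1e-12)

    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_forces_match_finite_differences(self, model,
                                             small_mixed_system, scheme,
                                             lam):
        sys_ = small_mixed_system
        spec = AlchemicalSpec(scheme=scheme, lam=lam)
        nl = build_neighbor_list(sys_, model.r_cut)
        analytic = forces(model, sys_, apply_alchemy(nl, sys_, spec))
        numeric = self.num_forces(model, sys_, spec)
        scale = max(1.0, np.abs(numeric).max())
        assert np.allclose(analytic, numeric, atol=1e-5 * scale)

    def test_net_force_is_zero(self, model, small_mixed_system):
        sys_ = small_mixed_system
        nl = build_neighbor_list(sys_, model.r_cut)
        f = forces(model, sys_, apply_alchemy(nl, sys_, AlchemicalSpec(
            scheme=4, lam=0.4)))
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_overlapping_atoms_error(self, model):
        sys_ = ParticleSystem(positions=[[1, 1, 1], [1, 1, 1]],
                              species=["W", "W"], masses=[18.0] * 2,
                              box=(20.0,) * 3)
        nl = build_neighbor_list(sys_, 5.0)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec())
        with pytest.raises(ValueError, match="overlap"):
            forces(model, sys_, anl)


class TestHarmonicAndComposite:
    def test_harmonic_pair_energy(self):
        model = HarmonicPairPotential(
            params={frozenset(("A", "D")): (4.0, 1.0)}, r_cut=5.0)
        sys_ = ParticleSystem(positions=[[0, 0, 0], [1.5, 0, 0]],
                              species=["A", "D"], masses=[1.0] * 2,
                              box=(20.0,) * 3)
        # well at 1.0, d=1.5, switch inactive below 4 A
        assert plain_energy(model, sys_) == pytest.approx(
            0.5 * 4.0 * 0.5 ** 2)

    def test_composite_sums_components(self, model):
        harm = HarmonicPairPotential(
            params={frozenset(("W",)): (1.0, 2.8)}, r_cut=5.0)
        comp = CompositePotential(components=(model, harm))
        sys_ = random_system(10, 12.0, seed=9)
        assert plain_energy(comp, sys_) == pytest.approx(
            plain_energy(model, sys_) + plain_energy(harm, sys_))

    def test_composite_requires_shared_cutoff(self, model):
        harm = HarmonicPairPotential(params={}, r_cut=4.0)
        with pytest.raises(ValueError):
            CompositePotential(components=(model, harm))


class TestFlatBottomRestraint:
    def make(self, r):
        sys_ = ParticleSystem(positions=[[10 + r, 10, 10]], species=["V"],
                              masses=[10.0], box=(20.0,) * 3)
        rst = FlatBottomRestraint(atom=0, anchor_point=[10, 10, 10],
                                  r0=2.0, kf=10.0)
        return rst, sys_

    @pytest.mark.parametrize("r,expected", [
        (1.0, 0.0),     # inside the well
        (2.0, 0.0),     # at the boundary
        (3.0, 5.0),     # 0.5 * 10 * 1^2
    ])
    def test_energy(self, r, expected):
        rst, sys_ = self.make(r)
        assert restraint_energy(rst, sys_) == pytest.approx(expected)

    def test_forces_match_finite_differences(self):
        rst, sys_ = self.make(3.3)
        h = 1e-6
        f = restraint_forces(rst, sys_)
        for k in range(3):
            pos = sys_.positions.copy()
            pos[0, k] += h
            ep = restraint_energy(rst, sys_.with_positions(pos))
            pos[0, k] -= 2 * h
            em = restraint_energy(rst, sys_.with_positions(pos))
            assert f[0, k] == pytest.approx(-(ep - em) / (2 * h), abs=1e-5)

    def test_anchor_atom_reaction_force(self):
        sys_ = ParticleSystem(positions=[[0, 0, 0], [4, 0, 0]],
                              species=["V", "S"], masses=[10.0, 16.0],
                              box=(20.0,) * 3)
        rst = FlatBottomRestraint(atom=0, anchor_atom=1, r0=2.0, kf=10.0)
        f = restraint_forces(rst, sys_)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
        assert f[0, 0] > 0  # pulled toward the anchor

    def test_requires_exactly_one_anchor(self):
        with pytest.raises(ValueError):
            FlatBottomRestraint(atom=0, r0=1.0, kf=1.0)
        with pytest.raises(ValueError):
            FlatBottomRestraint(atom=0, r0=1.0, kf=1.0,
                                anchor_point=[0, 0, 0], anchor_atom=1)
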