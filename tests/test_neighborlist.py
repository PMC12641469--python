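"""Neighbor-list construction, masking and lambda-shifting schemes."""

import numpy as np
import pytest

from nlfep.neighborlist import (SCHEMES, AlchemicalSpec, apply_alchemy,
                                build_neighbor_list, mask_atoms,
                                shift_chain_factor, shift_distance,
                                single_atom_selector)
from nlfep.system import ParticleSystem, minimum_image

from conftest import random_system

EPS = 1e-4


def two_atom_system(distance):
    return ParticleSystem(
        positions=[[1.0, 1.0, 1.0], [1.0 + distance, 1.0, 1.0]],
        species=["W", "W"], masses=[18.0, 18.0], box=(20.0,) * 3,
    )


def brute_force_pairs(system, r_cut):
    """Independent all-pairs oracle for list construction."""
    out = {}
    n = system.n_atoms
    for a in range(n):
        for b in range(a + 1, n):
            delta = minimum_image(system.positions[a] - system.positions[b],
                                  system.box)
            d = np.linalg.norm(delta)
            if d < r_cut:
                out[(a, b)] = d
    return out


class TestBuild:
    def test_single_pair_within_cutoff(self):
        nl = build_neighbor_list(two_atom_system(3.0), 5.0)
        assert len(nl) == 1
        assert nl.d[0] == pytest.approx(3.0)

    def test_pair_beyond_cutoff_excluded(self):
        nl = build_neighbor_list(two_atom_system(6.0), 5.0)
        assert len(nl) == 0

    def test_box_too_small_rejected(self):
        sys_ = ParticleSystem(positions=np.zeros((1, 3)), species=["W"],
                              masses=[18.0], box=(9.0, 20, 20))
        with pytest.raises(ValueError, match="2\\*r_cut"):
            build_neighbor_list(sys_, 5.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        sys_ = random_system(50, 12.0, seed)
        nl = build_neighbor_list(sys_, 5.0)
        oracle = brute_force_pairs(sys_, 5.0)
        assert nl.pairs() == set(oracle)
        for (a, b), d in zip(zip(nl.i, nl.j), nl.d):
            assert d == pytest.approx(oracle[(int(a), int(b))], abs=1e-10)

    def test_distances_match_displacement_norms(self):
        nl = build_neighbor_list(random_system(50, 12.0, 3), 5.0)
        assert np.allclose(nl.d, np.linalg.norm(nl.disp, axis=1))
        assert np.all(nl.i != nl.j)
        assert np.all(nl.d < 5.0)


class TestMasking:
    def setup_method(self):
        # A,B close; B,D close; D,w4 close -> entries {(A,B),(B,D),(D,w4)}
        self.sys = ParticleSystem(
            positions=[[0, 0, 0], [3, 0, 0], [3, 3, 0], [3, 3, 3]],
            species=["A", "B", "D", "w"], masses=np.ones(4),
            box=(20.0,) * 3,
        )
        self.nl = build_neighbor_list(self.sys, 4.0)

    def test_masking_removes_all_entries_of_atom(self):
        assert self.nl.pairs() == {(0, 1), (1, 2), (2, 3)}
        masked = mask_atoms(self.nl, {2})
        assert masked.pairs() == {(0, 1)}

    def test_empty_mask_is_identity(self):
        masked = mask_atoms(self.nl, set())
        assert masked.pairs() == self.nl.pairs()

    def test_masking_everything_empties_list(self):
        assert len(mask_atoms(self.nl, {0, 1, 2, 3})) == 0


class TestShiftDistance:
    def test_scheme1_shifts_by_cutoff_at_lambda_one(self):
        spec = AlchemicalSpec(scheme=1, lam=1.0)
        assert shift_distance(2.0, 5.0, spec) == pytest.approx(7.0)

    def test_scheme3_pythagorean(self):
        spec = AlchemicalSpec(scheme=3, lam=1.0)
        assert shift_distance(3.0, 4.0, spec) == pytest.approx(5.0)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_lambda_zero_exact_identity(self, scheme):
        spec = AlchemicalSpec(scheme=scheme, lam=0.0, epsilon=EPS)
        for d in np.linspace(0.0, 4.999, 23):
            assert shift_distance(d, 5.0, spec) == d

    def test_scheme2_halfway(self):
        spec = AlchemicalSpec(scheme=2, lam=0.5, epsilon=EPS)
        assert shift_distance(2.0, 5.0, spec) == \
            pytest.approx(3.5 + 0.5 * EPS, abs=1e-12)

    def test_distance_at_or_beyond_cutoff_rejected(self):
        spec = AlchemicalSpec(scheme=1, lam=0.5)
        with pytest.raises(ValueError):
            shift_distance(5.0, 5.0, spec)
        with pytest.raises(ValueError):
            shift_distance(6.0, 5.0, spec)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_grid_properties(self, scheme):
        """Identity at 0, clears cutoff at 1, monotone non-decreasing."""
        r_cut = 5.0
        d_grid = np.linspace(0.0, r_cut - 1e-6, 60)
        lam_grid = np.linspace(0.0, 1.0, 101)
        prev = None
        for lam in lam_grid:
            spec = AlchemicalSpec(scheme=scheme, lam=lam, epsilon=EPS)
            dp = shift_distance(d_grid, r_cut, spec)
            assert np.all(dp >= d_grid - 1e-12)
            if prev is not None:
                assert np.all(dp >= prev - 1e-12)
            prev = dp
        # end state
        spec1 = AlchemicalSpec(scheme=scheme, lam=1.0, epsilon=EPS)
        dp1 = shift_distance(d_grid, r_cut, spec1)
        assert np.all(dp1 >= r_cut)
        if scheme in (1, 3):
            # strict clearance for every physical (d > 0) pair
            assert np.all(dp1[d_grid > 0] > r_cut)
        else:
            assert np.all(dp1 - r_cut <= 2 * EPS)
            assert np.all(dp1 - r_cut > 0)

    def test_schemes_1_and_3_agree_at_zero_and_clear_cutoff(self):
        d = np.linspace(0.05, 4.99, 40)
        s1 = shift_distance(d, 5.0, AlchemicalSpec(scheme=1, lam=0.0))
        s3 = shift_distance(d, 5.0, AlchemicalSpec(scheme=3, lam=0.0))
        assert np.allclose(s1, s3)
        s1 = shift_distance(d, 5.0, AlchemicalSpec(scheme=1, lam=1.0))
        s3 = shift_distance(d, 5.0, AlchemicalSpec(scheme=3, lam=1.0))
        assert np.all(s1 > 5.0) and np.all(s3 > 5.0)


class TestChainFactor:
    def test_scheme1_is_unity(self):
        for lam in (0.0, 0.4, 1.0):
            spec = AlchemicalSpec(scheme=1, lam=lam)
            assert shift_chain_factor(2.5, 5.0, spec) == 1.0

    def test_scheme2_is_one_minus_lambda(self):
        spec = AlchemicalSpec(scheme=2, lam=0.3)
        assert shift_chain_factor(2.0, 5.0, spec) == pytest.approx(0.7)

    def test_scheme3_ratio(self):
        spec = AlchemicalSpec(scheme=3, lam=1.0)
        assert shift_chain_factor(3.0, 4.0, spec) == pytest.approx(3.0 / 5.0)

    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_matches_finite_differences(self, scheme, lam):
        spec = AlchemicalSpec(scheme=scheme, lam=lam, epsilon=EPS)
        h = 1e-6
        for d in np.linspace(0.5, 4.4, 9):
            fd = (shift_distance(d + h, 5.0, spec)
                  - shift_distance(d - h, 5.0, spec)) / (2 * h)
            cf = shift_chain_factor(d, 5.0, spec)
            assert cf == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_limit_at_zero_distance(self):
        # schemes 3/4 have vanishing radial derivative at d=0 when lam>0
        assert shift_chain_factor(
            0.0, 5.0, AlchemicalSpec(scheme=3, lam=0.5)) == 0.0
        assert shift_chain_factor(
            0.0, 5.0, AlchemicalSpec(scheme=4, lam=0.5)) == 0.0
        assert shift_chain_factor(
            0.0, 5.0, AlchemicalSpec(scheme=3, lam=0.0)) == 1.0


class TestApplyAlchemy:
    def make_system(self):
        # 2 solute atoms + 2 solvent atoms
        return ParticleSystem(
            positions=[[5, 5, 5], [7, 5, 5], [5, 8, 5], [9, 9, 9]],
            species=["S", "S", "W", "W"], masses=np.ones(4),
            box=(20.0,) * 3, solute_indices={0, 1},
        )

    def test_lambda_zero_identity(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec(scheme=2, lam=0.0))
        assert anl.pairs() == nl.pairs()
        assert np.array_equal(anl.d_mod, anl.d)
        assert np.all(anl.chain == 1.0)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_lambda_one_removes_cross_pairs(self, scheme):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec(scheme=scheme, lam=1.0))
        sol = sys_.is_solute_mask()
        for a, b in anl.pairs():
            assert sol[a] == sol[b], "cross pair survived at lambda=1"
        assert np.all(anl.d_mod < anl.r_cut)

    def test_intrasolute_pair_unmodified_at_any_lambda(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        anl = apply_alchemy(nl, sys_, AlchemicalSpec(scheme=2, lam=0.7))
        for n, (a, b) in enumerate(zip(anl.i, anl.j)):
            if (a, b) == (0, 1):
                assert anl.d_mod[n] == anl.d[n] == pytest.approx(2.0)
                assert anl.chain[n] == 1.0

    def test_commutes_with_masking(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        spec = AlchemicalSpec(scheme=3, lam=0.6, masked_atoms={2})
        via_spec = apply_alchemy(nl, sys_, spec)
        via_mask = apply_alchemy(mask_atoms(nl, {2}), sys_,
                                 AlchemicalSpec(scheme=3, lam=0.6))
        assert via_spec.pairs() == via_mask.pairs()
        assert np.allclose(np.sort(via_spec.d_mod), np.sort(via_mask.d_mod))

    def test_masked_pairs_removed(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        spec = AlchemicalSpec(scheme=1, lam=0.0,
                              masked_pairs={(1, 0)})
        anl = apply_alchemy(nl, sys_, spec)
        assert (0, 1) not in anl.pairs()

    def test_dual_spec_claims_disjoint_pairs(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        specs = (
            AlchemicalSpec(scheme=2, lam=1.0,
                           pair_selector=single_atom_selector(0),
                           masked_pairs={(0, 1)}),
            AlchemicalSpec(scheme=2, lam=0.0,
                           pair_selector=single_atom_selector(1)),
        )
        anl = apply_alchemy(nl, sys_, specs)
        # atom 0 fully decoupled, atom 1 fully coupled, (0,1) hidden
        assert all(0 not in p for p in anl.pairs())
        assert any(1 in p for p in anl.pairs())

    def test_invalid_masked_index_rejected(self):
        sys_ = self.make_system()
        nl = build_neighbor_list(sys_, 5.0)
        with pytest.raises(IndexError):
            apply_alchemy(nl, sys_, AlchemicalSpec(masked_atoms={99}))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            AlchemicalSpec(scheme=5)
        with pytest.raises(ValueError):
            AlchemicalSpec(lam=1.5)
        with pytest.raises(ValueError):
            AlchemicalSpec(epsilon=0.0)
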