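"""Kinship, the five pairing rules, and the annealing optimizer."""
import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import (balanced_allocations, enumerate_mate_optimum,
                     recursive_kinship)
from matesim import (ConfigurationError, PedigreeError, inbreeding_coefficients,
                     kinship_matrix, make_plan, pair_assortative,
                     pair_inbreeding_opt, pair_random)


class TestKinshipMatrix:
    def test_founders_and_full_sibs(self):
        #  0,1 founders; 2,3 full sibs; 4 their offspring
        sire = np.array([-1, -1, 0, 0, 2])
        dam = np.array([-1, -1, 1, 1, 3])
        K = kinship_matrix(sire, dam)
        assert K[0, 1] == 0.0 and K[0, 0] == 0.5
        assert K[2, 3] == pytest.approx(0.25)
        F = inbreeding_coefficients(sire, dam)
        assert F[4] == pytest.approx(0.25)  # offspring F = parents' kinship

    def test_six_animal_pedigree_hand_values(self):
        # 0,1 founders; 2,3 full sibs; 4,5 full sibs bred from 2 x 3
        sire = np.array([-1, -1, 0, 0, 2, 2])
        dam = np.array([-1, -1, 1, 1, 3, 3])
        expected = np.array([
            [0.5, 0.0, 0.25, 0.25, 0.25, 0.25],
            [0.0, 0.5, 0.25, 0.25, 0.25, 0.25],
            [0.25, 0.25, 0.5, 0.25, 0.375, 0.375],
            [0.25, 0.25, 0.25, 0.5, 0.375, 0.375],
            [0.25, 0.25, 0.375, 0.375, 0.625, 0.375],
            [0.25, 0.25, 0.375, 0.375, 0.375, 0.625],
        ])
        assert np.allclose(kinship_matrix(sire, dam), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_recursive_coancestry_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(5, n):
            sire[i], dam[i] = rng.integers(0, i, size=2)
        assert np.allclose(kinship_matrix(sire, dam),
                           recursive_kinship(sire, dam))

    def test_rejects_parent_after_offspring(self):
        with pytest.raises(PedigreeError):
            kinship_matrix(np.array([-1, 2]), np.array([-1, -1]))


class TestRandomPairing:
    def test_single_sire_takes_all_dams(self, rng):
        plan = pair_random([7], [1, 2, 3], rng)
        assert set(plan.sires.tolist()) == {7}
        plan.validate([7], [1, 2, 3])

    def test_full_scale_sire_balance(self, rng):
        sires = np.arange(50)
        dams = np.arange(50, 3550)
        plan = pair_random(sires, dams, rng)
        plan.validate(sires, dams)
        counts = np.bincount(plan.sires)
        assert np.all(counts == 70)

    def test_dam_multiset_preserved(self, rng):
        dams = np.array([5, 5, 6, 7])  # duplicates allowed in ids
        plan = pair_random([0, 1], dams, rng)
        assert sorted(plan.dams.tolist()) == sorted(dams.tolist())


class TestAssortativePairing:
    def test_rank_matching_two_by_two(self):
        plan = pair_assortative([0, 1], [10, 11], [1.0, 0.0], [0.9, -0.2], "+")
        assert plan.pairs == [(0, 10), (1, 11)]
        plan = pair_assortative([0, 1], [10, 11], [1.0, 0.0], [0.9, -0.2], "-")
        assert plan.pairs == [(0, 11), (1, 10)]

    def test_ties_broken_by_id(self):
        plan = pair_assortative([2, 1], [10, 11], [0.5, 0.5], [0.3, 0.3], "+")
        assert plan.pairs == [(1, 10), (2, 11)]

    @pytest.mark.parametrize("direction,pick", [("+", max), ("-", min)])
    def test_extremal_rank_products_by_enumeration(self, direction, pick):
        # 3 sires x 6 dams: positive assortment maximizes, negative minimizes,
        # the sum of sire-EBV x dam-EBV over pairs among balanced allocations
        rng = np.random.default_rng(0)
        s_ebv = rng.normal(size=3)
        d_ebv = rng.normal(size=6)
        plan = pair_assortative(np.arange(3), np.arange(6), s_ebv, d_ebv, direction)
        achieved = sum(s_ebv[s] * d_ebv[d] for s, d in plan.pairs)
        best = pick(sum(s_ebv[a[d]] * d_ebv[d] for d in range(6))
                    for a in balanced_allocations(3, 6))
        assert achieved == pytest.approx(best)

    def test_missing_or_nonfinite_ebv_rejected(self):
        with pytest.raises(ConfigurationError):
            pair_assortative([0, 1], [2, 3], [1.0], [0.0, 0.0], "+")
        with pytest.raises(ConfigurationError):
            pair_assortative([0, 1], [2, 3], [1.0, np.nan], [0.0, 0.0], "+")


class TestAnnealedPairing:
    def test_unrelated_candidates_trivially_optimal(self, rng):
        plan = pair_inbreeding_opt(np.arange(3), np.arange(3),
                                   np.zeros((3, 3)), "min", rng)
        assert plan.objective == 0.0

    @pytest.mark.parametrize("objective", ["min", "max"])
    def test_matches_exhaustive_optimum_100_restarts(self, objective):
        kin = np.array([[0.30, 0.10, 0.20],
                        [0.05, 0.25, 0.10],
                        [0.20, 0.15, 0.00]])
        best = enumerate_mate_optimum(kin, objective)
        for restart in range(100):
            plan = pair_inbreeding_opt(np.arange(3), np.arange(3), kin,
                                       objective, np.random.default_rng(restart))
            assert plan.objective == pytest.approx(best)

    def test_max_design_pairs_full_sibs(self):
        # sire i is a full sib of dam i (kinship .25), unrelated otherwise:
        # maximizing expected progeny F must reach the 0.25 textbook bound
        kin = 0.25 * np.eye(4)
        plan = pair_inbreeding_opt(np.arange(4), np.arange(4), kin, "max",
                                   np.random.default_rng(1))
        assert plan.objective == pytest.approx(0.25)
        assert np.allclose(plan.expected_F, 0.25)

    def test_best_so_far_is_monotone(self, rng):
        kin = np.abs(np.random.default_rng(3).normal(size=(5, 20))) / 4
        plan = pair_inbreeding_opt(np.arange(5), np.arange(20), kin, "min", rng)
        objs = [o for _, o in plan.trace]
        temps = [t for t, _ in plan.trace]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))
        assert all(a > b for a, b in zip(temps, temps[1:]))

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            pair_inbreeding_opt([], [1], np.zeros((0, 1)), "min", rng)


@given(n_sires=st.integers(1, 6), n_dams=st.integers(1, 40),
       design=st.sampled_from(["random", "min_inbreeding", "max_inbreeding"]),
       seed=st.integers(0, 2**20))
def test_every_design_satisfies_plan_invariants(n_sires, n_dams, design, seed):
    """Dam coverage and sire balance hold for any candidate-set shape."""
    rng = np.random.default_rng(seed)
    sires = np.arange(n_sires)
    dams = np.arange(n_sires, n_sires + n_dams)
    kin = rng.uniform(0.0, 0.5, size=(n_sires, n_dams))
    ebv = rng.normal(size=n_sires + n_dams)
    for d in (design, "assortative+", "assortative-"):
        plan = make_plan(d, sires, dams, rng, sire_ebv=ebv[:n_sires],
                         dam_ebv=ebv[n_sires:], kinship_sd=kin)
        plan.validate(sires, dams)
        if plan.expected_F is not None:
            assert np.all((plan.expected_F >= 0) & (plan.expected_F <= 1))


def test_plan_exports_pair_table(rng):
    plan = pair_random(np.arange(3), np.arange(3, 12), rng)
    frame = plan.to_frame()
    assert list(frame.columns) == ["sire", "dam", "expected_progeny_F"]
    assert len(frame) == 9
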