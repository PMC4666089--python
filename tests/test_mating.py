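"""The B/B′ matrices, the sequential rule, and the four scheme drivers."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herdmate.mating import (
    InfeasibleAllocation,
    adjust_for_recessives,
    assign_matings,
    build_b_matrix,
    prob_affected,
    sequential_allocate,
)
from herdmate.scenarios import RecessiveLocus, Scenario, loci_from_rows
from herdmate.synthetic import toy_population

from .oracles import greedy_allocation_reference


class TestProbAffected:
    @pytest.mark.parametrize(
        "sire, dam, expected",
        [
            (1, 1, 0.25),  # carrier × carrier
            (2, 1, 0.5),   # affected × carrier
            (1, 2, 0.5),
            (2, 2, 1.0),   # affected × affected
            (0, 2, 0.0),   # non-carrier transmits no minor allele
            (0, 0, 0.0),
            (0, 1, 0.0),
        ],
    )
    def test_mendelian_table(self, sire, dam, expected):
        assert prob_affected(sire, dam) == expected

    @pytest.mark.parametrize("bad", [-1, 3, 0.5])
    def test_rejects_invalid_genotype(self, bad):
        with pytest.raises(ValueError):
            prob_affected(bad, 1)


@pytest.fixture
def flat_population(rng):
    """2 bulls + 3 cows, one locus, everyone heterozygous, fixed TBV."""
    loci = loci_from_rows([("L", 0.5, 40, True)])
    tbv = np.array([300.0, 0.0, 0.0, 0.0, 0.0])
    return toy_population(2, 3, loci, np.ones((5, 1)), rng, tbv=tbv), loci


class TestBMatrix:
    def test_parent_average_no_inbreeding(self, flat_population):
        pop, _ = flat_population
        b = build_b_matrix(np.array([1]), np.array([3]), pop, pop.kinship, 25.0)
        assert b[0, 0] == pytest.approx(150.0)  # 0.5·(300+0), F = 0

    def test_percent_convention(self, flat_population):
        # F = 0.0625 and λ = $25/1 % → penalty 25·6.25 = $156.25
        pop, _ = flat_population

        class FixedF:
            def matrix(self, bulls, cows):
                return np.full((len(bulls), len(cows)), 0.0625)

        b = build_b_matrix(np.array([1]), np.array([3]), pop, FixedF(), 25.0)
        assert b[0, 0] == pytest.approx(150.0 - 156.25)  # = −6.25

    def test_lambda_zero_gives_plain_parent_average(self, flat_population):
        pop, _ = flat_population
        bulls, cows = np.array([1, 2]), np.array([3, 4, 5])
        b = build_b_matrix(bulls, cows, pop, pop.kinship, 0.0)
        pa = 0.5 * (pop.tbv[bulls - 1][:, None] + pop.tbv[cows - 1][None, :])
        np.testing.assert_allclose(b, pa)

    def test_empty_lists_rejected(self, flat_population):
        pop, _ = flat_population
        with pytest.raises(ValueError):
            build_b_matrix(np.array([]), np.array([3]), pop, pop.kinship, 25.0)


class TestRecessiveAdjustment:
    def test_carrier_pair_penalty(self, flat_population):
        # carrier × carrier at a $40 locus → 0.25·40 = $10 subtracted
        pop, loci = flat_population
        bulls, cows = np.array([1, 2]), np.array([3, 4, 5])
        b = build_b_matrix(bulls, cows, pop, pop.kinship, 25.0)
        b2 = adjust_for_recessives(b, bulls, cows, pop, loci)
        np.testing.assert_allclose(b2, b - 10.0)

    def test_desirable_recessive_raises_b(self, rng):
        # red coat color: v = −20, carrier × carrier → B′ = B + 5
        loci = loci_from_rows([("Red", 0.5, -20, False)])
        pop = toy_population(1, 1, loci, np.ones((2, 1)), rng)
        bulls, cows = np.array([1]), np.array([2])
        b = build_b_matrix(bulls, cows, pop, pop.kinship, 25.0)
        b2 = adjust_for_recessives(b, bulls, cows, pop, loci)
        assert b2[0, 0] == pytest.approx(b[0, 0] + 5.0)

    def test_no_shared_carriers_is_identity(self, rng):
        loci = loci_from_rows([("L", 0.5, 40, True)])
        pop = toy_population(1, 1, loci, np.array([[1], [0]]), rng)
        b = build_b_matrix(np.array([1]), np.array([2]), pop, pop.kinship, 25.0)
        b2 = adjust_for_recessives(b, np.array([1]), np.array([2]), pop, loci)
        np.testing.assert_allclose(b2, b)

    def test_zero_values_are_identity(self, rng):
        loci = loci_from_rows([("L", 0.5, 0, True)])
        pop = toy_population(2, 2, loci, np.ones((4, 1)), rng)
        bulls, cows = np.array([1, 2]), np.array([3, 4])
        b = build_b_matrix(bulls, cows, pop, pop.kinship, 25.0)
        np.testing.assert_allclose(adjust_for_recessives(b, bulls, cows, pop, loci), b)

    def test_locus_count_mismatch(self, flat_population):
        pop, loci = flat_population
        with pytest.raises(ValueError, match="mismatch"):
            adjust_for_recessives(np.zeros((1, 1)), np.array([1]), np.array([3]), pop, loci * 2)


class TestSequentialAllocate:
    def test_hand_trace(self):
        # dominant bull takes cows until his cap, then the next bull steps in
        b = np.array([[5.0, 5.0, 5.0], [1.0, 1.0, 1.0]])
        assigned, used = sequential_allocate(b, np.array([1, 2]), np.array([10, 11, 12]), cap=2)
        np.testing.assert_array_equal(assigned, [1, 1, 2])
        assert used == {1: 2, 2: 1}

    def test_unlimited_dominant_bull_takes_all(self):
        b = np.array([[9.0, 9.0, 9.0], [1.0, 1.0, 1.0]])
        assigned, _ = sequential_allocate(b, np.array([1, 2]), np.array([10, 11, 12]), cap=100)
        np.testing.assert_array_equal(assigned, [1, 1, 1])

    def test_ties_break_to_lowest_bull_id(self):
        b = np.zeros((3, 2))
        assigned, _ = sequential_allocate(b, np.array([7, 3, 5]), np.array([1, 2]), cap=1)
        np.testing.assert_array_equal(assigned, [3, 5])

    def test_cows_processed_in_ascending_id_order(self):
        # cow 1 (second column) is served first and takes the good bull
        b = np.array([[1.0, 9.0], [0.0, 8.0]])
        assigned, _ = sequential_allocate(b, np.array([1, 2]), np.array([2, 1]), cap=1)
        # column order: cow 1 → bull 1 (B=9); cow 2 → bull 2 (bull 1 at cap)
        np.testing.assert_array_equal(assigned, [2, 1])

    def test_infeasible_names_cow(self):
        b = np.zeros((1, 3))
        with pytest.raises(InfeasibleAllocation, match="cow 12"):
            sequential_allocate(b, np.array([1]), np.array([10, 11, 12]), cap=2)

    def test_carries_usage_across_calls(self):
        b = np.zeros((1, 1))
        assigned, used = sequential_allocate(b, np.array([1]), np.array([10]), cap=2)
        assigned, used = sequential_allocate(b, np.array([1]), np.array([11]), cap=2, matings_used=used)
        assert used == {1: 2}
        with pytest.raises(InfeasibleAllocation):
            sequential_allocate(b, np.array([1]), np.array([12]), cap=2, matings_used=used)

    @given(st.integers(0, 999))
    def test_matches_bruteforce_greedy(self, seed):
        rng = np.random.default_rng(seed)
        nb, nc = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        cap = int(rng.integers(1, nc + 1))
        if nb * cap < nc:
            cap = int(np.ceil(nc / nb))
        b = np.round(rng.normal(size=(nb, nc)), 1)  # coarse values force ties
        bulls = rng.choice(np.arange(1, 50), size=nb, replace=False)
        cows = rng.choice(np.arange(50, 120), size=nc, replace=False)
        ours, _ = sequential_allocate(b, bulls, cows, cap)
        ref = greedy_allocation_reference(b, bulls, cows, cap)
        np.testing.assert_array_equal(ours, ref)


def _scheme_scenario(loci, scheme, **kw):
    defaults = dict(
        n_base_bulls=10, n_base_cows=40, n_herds=4, max_bulls=20, max_cows=80,
        max_matings_per_bull=50, years=3, replicates=1, scheme=scheme, seed=3,
    )
    defaults.update(kw)
    return Scenario(loci=loci, **defaults)


class TestAssignMatings:
    def test_truncation_keeps_floor_fraction(self, rng):
        loci = loci_from_rows([("L", 0.1, 40, True)])
        pop = toy_population(10, 30, loci, np.array([0.1]), rng, n_herds=3)
        s = _scheme_scenario(loci, "truncation")
        plan = assign_matings("truncation", pop, s, rng)
        # 10 bulls × 10 % → exactly 1 eligible sire
        assert set(plan.bull_ids) == {int(np.argmax(pop.tbv[:10]) + 1)}

    def test_pryce_portfolio_size(self, rng):
        # 40 live bulls → ceil(0.2·40) = 8 sampled < 50 cap → 8 sires per herd
        loci = loci_from_rows([("L", 0.1, 40, True)])
        pop = toy_population(40, 30, loci, np.array([0.1]), rng, n_herds=1)
        s = _scheme_scenario(loci, "pryce", n_base_bulls=40, max_bulls=40)
        plan = assign_matings("pryce", pop, s, rng)
        evaluated_bulls = np.unique(plan.pair_bull)
        assert len(evaluated_bulls) == 8

    def test_random_respects_capacity(self, rng):
        loci = loci_from_rows([("L", 0.1, 40, True)])
        pop = toy_population(2, 30, loci, np.array([0.1]), rng)
        s = _scheme_scenario(loci, "random", n_base_bulls=2, n_base_cows=30,
                             max_matings_per_bull=20)
        plan = assign_matings("random", pop, s, rng)
        plan.validate(cap=20)
        assert len(plan) == 30

    def test_random_infeasible_when_over_capacity(self, rng):
        loci = loci_from_rows([("L", 0.1, 40, True)])
        pop = toy_population(2, 30, loci, np.array([0.1]), rng)
        s = _scheme_scenario(loci, "random", n_base_bulls=2, n_base_cows=30,
                             max_matings_per_bull=10)
        with pytest.raises(InfeasibleAllocation):
            assign_matings("random", pop, s, rng)

    @pytest.mark.parametrize("scheme", ["random", "truncation", "pryce", "modified_pryce"])
    def test_every_cow_gets_one_bull_from_eligible_set(self, rng, scheme):
        loci = loci_from_rows([("L", 0.3, 40, True)])
        pop = toy_population(12, 60, loci, np.array([0.3]), rng, n_herds=4)
        s = _scheme_scenario(loci, scheme, n_base_bulls=12, n_base_cows=60)
        plan = assign_matings(scheme, pop, s, rng)
        plan.validate()
        assert len(plan) == 60
        assert set(plan.cow_ids) == set(range(13, 73))
        assert set(plan.bull_ids) <= set(range(1, 13))

    def test_pryce_lambda_zero_equals_raw_parent_average(self, rng):
        # founders only (F ≡ 0) and no penalty → allocation on plain PA
        loci = loci_from_rows([("L", 0.0, 0, True)])
        pop = toy_population(6, 20, loci, np.array([0.0]), rng, n_herds=2)
        s = _scheme_scenario(
            loci, "pryce", n_base_bulls=6, n_base_cows=20,
            lambda_inbreeding=0.0, herd_sample_fraction=1.0,
        )
        plan_a = assign_matings("pryce", pop, s, np.random.default_rng(0))
        plan_b = assign_matings("modified_pryce", pop, s, np.random.default_rng(0))
        np.testing.assert_array_equal(plan_a.bull_ids, plan_b.bull_ids)

    def test_modified_scheme_avoids_carrier_pairs(self, rng):
        # one high-frequency costly lethal: the value adjustment can only
        # demote carrier×carrier pairs relative to the plain scheme
        loci = loci_from_rows([("L", 0.5, 400, True)])
        pop = toy_population(10, 60, loci, np.array([0.5]), rng, n_herds=2)
        s = _scheme_scenario(loci, "pryce", n_base_bulls=10, n_base_cows=60,
                             herd_sample_fraction=1.0)

        def carrier_matings(plan):
            g = pop.genotypes
            return int(
                ((g[plan.bull_ids - 1, 0] > 0) & (g[plan.cow_ids - 1, 0] > 0)).sum()
            )

        plain = assign_matings("pryce", pop, s, np.random.default_rng(1))
        adjusted = assign_matings("modified_pryce", pop, s, np.random.default_rng(1))
        assert carrier_matings(adjusted) <= carrier_matings(plain)

    def test_plan_records_f_and_penalty(self, rng):
        loci = loci_from_rows([("L", 0.5, 40, True)])
        pop = toy_population(3, 9, loci, np.ones((12, 1)), rng)
        s = _scheme_scenario(loci, "modified_pryce", n_base_bulls=3, n_base_cows=9)
        plan = assign_matings("modified_pryce", pop, s, rng)
        np.testing.assert_allclose(plan.f_ij, 0.0)  # founders
        np.testing.assert_allclose(plan.sum_paa, 0.25)  # all Aa × Aa
        np.testing.assert_allclose(plan.penalty, 10.0)
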