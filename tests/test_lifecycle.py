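"""Reproduction, Mendelian sampling, culling order, and replicate runs."""

import numpy as np
import pytest

from herdmate.lifecycle import (
    cull,
    make_calf,
    make_calves,
    mendelian_sampling_variance,
    replicate_seeds,
    run_replicate,
    run_replicates,
    run_year,
)
from herdmate.population import BULL, COW
from herdmate.scenarios import Scenario, loci_from_rows
from herdmate.synthetic import toy_population

ONE_LOCUS = loci_from_rows([("L", 0.5, 40, True)])


def _scenario(loci=ONE_LOCUS, **kw):
    defaults = dict(
        n_base_bulls=5, n_base_cows=20, n_herds=2, max_bulls=10, max_cows=40,
        max_matings_per_bull=50, years=3, replicates=1, scheme="random", seed=0,
    )
    defaults.update(kw)
    return Scenario(loci=loci, **defaults)


class TestMendelianSampling:
    def test_variance_formula(self):
        # non-inbred parents halve the additive variance: 0.5·40,000 = 20,000
        assert mendelian_sampling_variance(0.0, 0.0, 40_000.0) == 20_000.0
        # fully inbred parents leave no segregation variance
        assert mendelian_sampling_variance(1.0, 1.0, 40_000.0) == 0.0
        assert mendelian_sampling_variance(0.25, 0.25, 40_000.0) == pytest.approx(15_000.0)

    def test_ms_standard_deviation_recovered(self, rng):
        # 10,000 calves of the same non-inbred pair: TBV spread is the MS
        # deviate, sample SD ≈ √20,000 ≈ 141.4
        pop = toy_population(1, 1, ONE_LOCUS, np.zeros((2, 1)), rng,
                             tbv=np.array([300.0, 0.0]))
        s = _scenario()
        n = 10_000
        ids = make_calves(
            pop, np.full(n, 1), np.full(n, 2), np.zeros(n), s.loci, s, rng,
            update_kinship=False,
        )
        tbv = pop.tbv[ids - 1]
        assert tbv.mean() == pytest.approx(150.0, abs=3 * 141.4 / np.sqrt(n))
        se_sd = 141.4 / np.sqrt(2 * (n - 1))  # asymptotic SE of a sample SD
        assert tbv.std(ddof=1) == pytest.approx(np.sqrt(20_000.0), abs=3 * se_sd)

    def test_carrier_cross_segregation(self, rng):
        # Aa × Aa: affected fraction 1/4 within 3·SE at 40,000 calves
        pop = toy_population(1, 1, ONE_LOCUS, np.ones((2, 1)), rng)
        s = _scenario()
        n = 40_000
        ids = make_calves(pop, np.full(n, 1), np.full(n, 2), np.zeros(n), s.loci, s, rng,
                          update_kinship=False)
        affected = (pop.genotypes[ids - 1, 0] == 2).mean()
        assert abs(affected - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)
        # affected calves of a lethal locus are created dead
        dead = ~pop.alive[ids - 1]
        np.testing.assert_array_equal(dead, pop.genotypes[ids - 1, 0] == 2)

    def test_heterozygote_transmits_half(self, rng):
        # 10⁵ gametes from an Aa sire (dam aa fixed): calf genotype − 1
        # recovers the sire's transmitted allele
        pop = toy_population(1, 1, ONE_LOCUS, np.array([[1], [2]]), rng)
        s = _scenario()
        n = 100_000
        ids = make_calves(pop, np.full(n, 1), np.full(n, 2), np.zeros(n), s.loci, s, rng,
                          update_kinship=False)
        transmitted = pop.genotypes[ids - 1, 0] - 1
        assert abs(transmitted.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_homozygous_reference_parents(self, rng):
        pop = toy_population(1, 1, ONE_LOCUS, np.zeros((2, 1)), rng)
        s = _scenario()
        calf = make_calf(pop, 1, 2, s, rng)
        assert calf.genotypes[0] == 0 and calf.alive

    def test_sex_ratio_binomial(self, rng):
        pop = toy_population(1, 1, ONE_LOCUS, np.zeros((2, 1)), rng)
        s = _scenario()
        n = 20_000
        ids = make_calves(pop, np.full(n, 1), np.full(n, 2), np.zeros(n), s.loci, s, rng,
                          update_kinship=False)
        frac = (pop.sex[ids - 1] == BULL).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_calf_inherits_dam_herd(self, rng):
        pop = toy_population(1, 4, ONE_LOCUS, np.zeros((5, 1)), rng, n_herds=4)
        s = _scenario()
        ids = make_calves(pop, np.full(4, 1), np.arange(2, 6), np.zeros(4), s.loci, s, rng)
        cow_calves = pop.sex[ids - 1] == COW
        np.testing.assert_array_equal(
            pop.herd[ids - 1][cow_calves], pop.herd[np.arange(1, 5)][cow_calves]
        )

    def test_rejects_dead_or_same_sex_parents(self, rng):
        pop = toy_population(2, 2, ONE_LOCUS, np.zeros((4, 1)), rng)
        s = _scenario()
        with pytest.raises(ValueError, match="sires must be bulls"):
            make_calf(pop, 1, 2, s, rng)  # id 2 is a bull
        pop.mark_dead(np.array([1]), "age")
        with pytest.raises(ValueError, match="dead"):
            make_calf(pop, 1, 3, s, rng)


class TestCulling:
    def test_bull_tbv_cull_keeps_best(self, rng):
        pop = toy_population(600, 5, ONE_LOCUS, np.array([0.0]), rng, birth_year=0)
        s = _scenario(n_base_bulls=500, n_base_cows=5, max_bulls=500, max_cows=40)
        pop.current_year = 1
        report = cull(pop, s, rng)
        assert report["tbv_cull"] == 100
        survivors = pop.live_ids(BULL)
        culled_tbv = pop.tbv[:600][~np.isin(np.arange(1, 601), survivors)]
        assert culled_tbv.max() <= pop.tbv[survivors - 1].min()

    def test_age_cull_at_maximum_age(self, rng):
        pop = toy_population(2, 2, ONE_LOCUS, np.array([0.0]), rng, birth_year=0)
        s = _scenario(n_base_bulls=2, n_base_cows=2, bull_max_age=10, cow_max_age=5)
        pop.current_year = 5
        cull(pop, s, rng)
        assert len(pop.live_ids(COW)) == 0  # cows reached age 5
        assert len(pop.live_ids(BULL)) == 2
        pop.current_year = 10
        report = cull(pop, s, rng)
        assert report["age"] == 2  # bulls reached age 10

    def test_no_culls_when_under_caps(self, rng):
        pop = toy_population(3, 10, ONE_LOCUS, np.array([0.0]), rng)
        s = _scenario(n_base_bulls=3, n_base_cows=10, involuntary_cull_rate=0.0)
        report = cull(pop, s, rng)
        assert report == {"age": 0, "tbv_cull": 0, "involuntary": 0, "random_cull": 0}
        assert len(pop.live_ids()) == 13

    def test_involuntary_rate(self, rng):
        pop = toy_population(1, 2000, ONE_LOCUS, np.array([0.0]), rng)
        s = _scenario(n_base_bulls=1, n_base_cows=2000, max_cows=4000,
                      involuntary_cull_rate=0.2)
        report = cull(pop, s, rng)
        assert abs(report["involuntary"] / 2000 - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000)


class TestRunYear:
    def test_zero_loci_no_embryo_deaths(self, rng):
        s = _scenario(loci=())
        from herdmate.population import build_base_population

        pop = build_base_population(s, rng)
        summary = run_year(pop, s, rng)
        assert summary.n_embryo_deaths == 0
        assert summary.n_matings > 0

    def test_absent_allele_stays_absent(self):
        # no mutation is modeled: maf 0 stays 0 every year
        s = _scenario(loci=loci_from_rows([("L", 0.0, 40, True)]), years=3)
        result = run_replicate(s, seed=4)
        assert all(su.allele_frequency["L"] == 0.0 for su in result.summaries)

    def test_caps_hold_and_dead_never_mated(self):
        s = _scenario(years=4, n_base_cows=30, max_cows=35, max_bulls=6)
        result = run_replicate(s, seed=8)
        for su in result.summaries:
            assert su.n_bulls <= s.max_bulls
            assert su.n_cows <= s.max_cows
            assert su.n_embryo_deaths <= su.n_matings

    def test_mean_inbreeding_nondecreasing_by_birth_year(self):
        s = _scenario(years=6, scheme="truncation", seed=2)
        result = run_replicate(s, seed=2)
        by_year = result.summaries[-1].mean_f_by_birth_year
        years = sorted(y for y in by_year if y >= 0)
        values = [by_year[y] for y in years]
        # closed population under selection: inbreeding accumulates
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestGeneticTrend:
    def test_random_mating_flat_truncation_positive(self):
        # bulls start at the cow mean and caps are non-binding, so no TBV
        # culling occurs: random mating has no selective force and the trend
        # is zero within replicate noise, while truncation selection on the
        # same conditions produces a clearly positive trend
        kwargs = dict(
            loci=(), years=6, n_base_bulls=30, n_base_cows=120, n_herds=4,
            max_bulls=100_000, max_cows=100_000, replicates=5, seed=10,
            bull_tbv_mean=0.0,
        )
        drifts = {}
        for scheme in ("random", "truncation"):
            results = run_replicates(_scenario(scheme=scheme, **kwargs))
            drifts[scheme] = np.array([
                r.summaries[-1].mean_tbv_cows - r.summaries[0].mean_tbv_cows
                for r in results
            ])
        rnd = drifts["random"]
        se = rnd.std(ddof=1) / np.sqrt(len(rnd))
        assert abs(rnd.mean()) < 4 * se
        assert drifts["truncation"].mean() > rnd.mean() + 4 * se


class TestReplicates:
    def test_determinism(self):
        s = _scenario(years=2, replicates=2, seed=123)
        a = run_replicates(s)
        b = run_replicates(s)
        for ra, rb in zip(a, b):
            assert ra.seed == rb.seed
            for sa, sb in zip(ra.summaries, rb.summaries):
                assert sa.allele_frequency == sb.allele_frequency
                assert sa.mean_tbv_cows == sb.mean_tbv_cows

    def test_replicate_count_and_seed_bounds(self):
        s = _scenario(years=1, replicates=1)
        assert len(run_replicates(s)) == 1
        seeds = replicate_seeds(99, 10)
        assert len(set(seeds)) == 10
        assert all(0 <= x < 2**31 for x in seeds)
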