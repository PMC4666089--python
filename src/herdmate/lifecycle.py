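"""The yearly simulation loop: reproduction, lethal deaths, and culling.

Each simulated year: mates are allocated under the scenario's scheme; every
mated cow produces one calf whose true breeding value is the parent average
plus a Mendelian-sampling deviate with variance ½·[1 − ½(f_S + f_D)]·σ_a²;
calves inherit one uniformly sampled allele per parent at each recessive
locus; calves homozygous for a lethal allele die at birth (they stay in the
registry and pedigree but never enter frequency counts or matings); finally
the population is culled, strictly in the order: age, then bull TBV /
cow involuntary+random culls to hold the caps. Generations overlap — parents
breed across multiple years until age-culled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mating import MatingPlan, assign_matings
from .population import BULL, COW, Animal, Population, allele_frequencies, build_base_population
from .scenarios import RecessiveLocus, Scenario

__all__ = [
    "YearSummary",
    "ReplicateResult",
    "mendelian_sampling_variance",
    "make_calf",
    "cull",
    "run_year",
    "run_replicate",
    "run_replicates",
    "replicate_seeds",
]


@dataclass
class YearSummary:
    """Aggregates recorded at the end of one simulated year."""

    year: int
    allele_frequency: dict[str, float]
    mean_tbv_bulls: float
    mean_tbv_cows: float
    n_bulls: int
    n_cows: int
    mean_f_by_birth_year: dict[int, float]
    n_matings: int
    n_embryo_deaths: int
    culls: dict[str, int] = field(default_factory=dict)

    @property
    def proportion_affected(self) -> float:
        """Share of this year's embryos lost to lethal recessive genotypes."""
        if self.n_matings == 0:
            return 0.0
        return self.n_embryo_deaths / self.n_matings


@dataclass
class ReplicateResult:
    """One replicate's year series plus optional final-year mating detail."""

    seed: int
    summaries: list[YearSummary]
    final_plan: MatingPlan | None = None

    def frequency_frame(self) -> pd.DataFrame:
        rows = [
            {"year": s.year, "locus": locus, "frequency": freq}
            for s in self.summaries
            for locus, freq in s.allele_frequency.items()
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [s.year for s in self.summaries],
                "n_bulls": [s.n_bulls for s in self.summaries],
                "n_cows": [s.n_cows for s in self.summaries],
                "mean_tbv_bulls": [s.mean_tbv_bulls for s in self.summaries],
                "mean_tbv_cows": [s.mean_tbv_cows for s in self.summaries],
                "n_matings": [s.n_matings for s in self.summaries],
                "n_embryo_deaths": [s.n_embryo_deaths for s in self.summaries],
                "proportion_affected": [s.proportion_affected for s in self.summaries],
                **{
                    f"culls_{c}": [s.culls.get(c, 0) for s in self.summaries]
                    for c in ("age", "tbv_cull", "involuntary", "random_cull")
                },
            }
        )


def mendelian_sampling_variance(f_sire: float, f_dam: float, additive_variance: float) -> float:
    """½·[1 − ½(f_S + f_D)]·σ_a² — parental inbreeding shrinks the variance."""
    return 0.5 * (1.0 - 0.5 * (f_sire + f_dam)) * additive_variance


def _transmit(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent row: the minor allele passes with probability g/2."""
    return (rng.random(genotypes.shape) < genotypes / 2.0).astype(np.int8)


def make_calves(
    population: Population,
    sires: np.ndarray,
    dams: np.ndarray,
    f_calf: np.ndarray,
    loci: tuple[RecessiveLocus, ...],
    scenario: Scenario,
    rng: np.random.Generator,
    update_kinship: bool = True,
) -> np.ndarray:
    """Create one calf per (sire, dam) pair; returns the new ids.

    ``f_calf`` is the precomputed coancestry of each pair (available from the
    mating plan). Lethal homozygotes are marked dead immediately.
    ``update_kinship=False`` skips registering calves in the live-kinship
    matrix — only for terminal offspring that will never breed (e.g. bulk
    segregation checks), since unregistered animals cannot be mated later.
    """
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    n = len(sires)
    si, di = sires - 1, dams - 1
    if not (population.alive[si].all() and population.alive[di].all()):
        raise ValueError("dead parent in mating list")
    if (population.sex[si] != BULL).any() or (population.sex[di] != COW).any():
        raise ValueError("sires must be bulls and dams cows")

    idx = population._append(n)
    ids = idx + 1
    pa = 0.5 * (population.tbv[si] + population.tbv[di])
    ms_sd = np.sqrt(
        mendelian_sampling_variance(
            population.f[si], population.f[di], scenario.additive_variance
        )
    )
    population.tbv[idx] = pa + rng.normal(0.0, 1.0, size=n) * ms_sd
    population.sex[idx] = np.where(rng.random(n) < 0.5, BULL, COW)
    population.birth_year[idx] = population.current_year
    # calves are born in their dam's herd; bulls carry no herd
    population.herd[idx] = np.where(
        population.sex[idx] == COW, population.herd[di], -1
    )
    population.sire[idx] = sires
    population.dam[idx] = dams
    population.f[idx] = f_calf
    geno = _transmit(population.genotypes[si], rng) + _transmit(
        population.genotypes[di], rng
    )
    population.genotypes[idx] = geno
    population.alive[idx] = True

    if update_kinship:
        for an, s, d in zip(ids, sires, dams):
            population.kinship.add_offspring(int(an), int(s), int(d))

    lethal = np.array([loc.lethal for loc in loci], dtype=bool)
    if lethal.any():
        affected = (geno[:, lethal] == 2).any(axis=1)
        if affected.any():
            population.mark_dead(ids[affected], "lethal_recessive")
    return ids


def make_calf(
    population: Population,
    sire_id: int,
    dam_id: int,
    scenario: Scenario,
    rng: np.random.Generator,
) -> Animal:
    """Create a single calf (convenience wrapper over :func:`make_calves`)."""
    f = population.kinship.coancestry(sire_id, dam_id)
    ids = make_calves(
        population,
        np.array([sire_id]),
        np.array([dam_id]),
        np.array([f]),
        scenario.loci,
        scenario,
        rng,
    )
    return population.animal(int(ids[0]))


def cull(
    population: Population, scenario: Scenario, rng: np.random.Generator
) -> dict[str, int]:
    """End-of-year culling, strictly ordered.

    Bulls: first for age (culled once age reaches ``bull_max_age`` at year
    end, so no bull is mated beyond the maximum age), then lowest-TBV-first
    down to ``max_bulls``. Cows: for age, then involuntarily (each survivor
    independently with ``involuntary_cull_rate``), then uniformly at random
    down to ``max_cows``. Carrier status never enters any cull.
    """
    report = {"age": 0, "tbv_cull": 0, "involuntary": 0, "random_cull": 0}

    bulls = population.live_ids(BULL)
    over = bulls[population.age(bulls) >= scenario.bull_max_age]
    population.mark_dead(over, "age")
    report["age"] += len(over)
    bulls = population.live_ids(BULL)
    excess = len(bulls) - scenario.max_bulls
    if excess > 0:
        worst = bulls[np.argsort(population.tbv[bulls - 1], kind="stable")[:excess]]
        population.mark_dead(worst, "tbv_cull")
        report["tbv_cull"] += excess

    cows = population.live_ids(COW)
    over = cows[population.age(cows) >= scenario.cow_max_age]
    population.mark_dead(over, "age")
    report["age"] += len(over)
    cows = population.live_ids(COW)
    if scenario.involuntary_cull_rate > 0 and len(cows):
        hit = cows[rng.random(len(cows)) < scenario.involuntary_cull_rate]
        population.mark_dead(hit, "involuntary")
        report["involuntary"] += len(hit)
        cows = population.live_ids(COW)
    excess = len(cows) - scenario.max_cows
    if excess > 0:
        victims = rng.choice(cows, size=excess, replace=False)
        population.mark_dead(victims, "random_cull")
        report["random_cull"] += excess
    return report


def _summarize(
    population: Population, plan_size: int, n_deaths: int, culls: dict[str, int]
) -> YearSummary:
    live = population.alive[: population.n]
    sex = population.sex[: population.n]
    tbv = population.tbv[: population.n]
    by = population.birth_year[: population.n]
    f = population.f[: population.n]
    bulls = live & (sex == BULL)
    cows = live & (sex == COW)
    mean_f: dict[int, float] = {}
    for year in np.unique(by[live]):
        mean_f[int(year)] = float(f[live & (by == year)].mean())
    return YearSummary(
        year=population.current_year,
        allele_frequency=allele_frequencies(population),
        mean_tbv_bulls=float(tbv[bulls].mean()) if bulls.any() else float("nan"),
        mean_tbv_cows=float(tbv[cows].mean()) if cows.any() else float("nan"),
        n_bulls=int(bulls.sum()),
        n_cows=int(cows.sum()),
        mean_f_by_birth_year=mean_f,
        n_matings=plan_size,
        n_embryo_deaths=n_deaths,
        culls=culls,
    )


def run_year(
    population: Population,
    scenario: Scenario,
    rng: np.random.Generator,
    keep_plan: bool = False,
) -> YearSummary | tuple[YearSummary, MatingPlan]:
    """Advance the simulation by one year."""
    population.current_year += 1
    plan = assign_matings(scenario.scheme, population, scenario, rng)
    calf_ids = make_calves(
        population, plan.bull_ids, plan.cow_ids, plan.f_ij, scenario.loci, scenario, rng
    )
    n_deaths = int((~population.alive[calf_ids - 1]).sum())
    culls = cull(population, scenario, rng)
    population.kinship.compact(population.live_ids())
    summary = _summarize(population, len(plan), n_deaths, culls)
    return (summary, plan) if keep_plan else summary


def _year_zero_summary(population: Population) -> YearSummary:
    return _summarize(population, 0, 0, {})


def run_replicate(
    scenario: Scenario,
    seed: int,
    keep_final_plan: bool = False,
    progress=None,
) -> ReplicateResult:
    """Run one replicate from base population through ``scenario.years``.

    The series includes a year-0 summary of the freshly built base
    population, so frequency trajectories start at the initial MAF.
    """
    rng = np.random.default_rng(seed)
    population = build_base_population(scenario, rng)
    summaries = [_year_zero_summary(population)]
    final_plan = None
    for year in range(1, scenario.years + 1):
        keep = keep_final_plan and year == scenario.years
        out = run_year(population, scenario, rng, keep_plan=keep)
        summary, final_plan = out if keep else (out, final_plan)
        summaries.append(summary)
        if progress is not None:
            progress(summary)
    return ReplicateResult(seed=seed, summaries=summaries, final_plan=final_plan)


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (below 2³¹) for each replicate."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_replicates(
    scenario: Scenario,
    keep_final_plan: bool = False,
    progress=None,
) -> list[ReplicateResult]:
    """Run ``scenario.replicates`` independent replicates.

    Child seeds derive deterministically from ``scenario.seed``, so the same
    scenario reproduces bit-identically.
    """
    if scenario.replicates < 1:
        raise ValueError("replicates must be >= 1")
    seeds = replicate_seeds(scenario.seed, scenario.replicates)
    results = []
    for r, seed in enumerate(seeds):
        try:
            results.append(
                run_replicate(scenario, seed, keep_final_plan=keep_final_plan, progress=progress)
            )
        except Exception as exc:
            raise RuntimeError(f"replicate {r} (seed {seed}) failed: {exc}") from exc
    return results
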