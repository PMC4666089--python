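"""Mate allocation: the four schemes and the sequential assignment rule.

The selection objective of a prospective mating of bull *i* and cow *j* is

    B_ij = ½·(TBV_i + TBV_j) − λ·F_ij,

the parent average penalized by the expected inbreeding depression; λ is
priced per 1 % of calf inbreeding, so the pedigree coefficient F_ij enters
as a percentage. The modified scheme further subtracts the expected economic
cost of recessive genotypes,

    B′_ij = B_ij − Σ_r P(aa)_r · v_r,

where P(aa)_r is the probability that the calf is homozygous recessive at
locus *r* (0, ¼, ½, or 1 given parental genotypes) and v_r its dollar value;
negative values (desirable recessives such as red coat color) *raise* B′.

Cows are then processed in a fixed order and each receives the remaining
bull with the highest B in her column, subject to a per-bull cap on yearly
matings — the published sequential (greedy, order-dependent) rule, not an
optimizing assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .population import BULL, COW, Population
from .scenarios import RecessiveLocus, Scenario

__all__ = [
    "MatingPlan",
    "InfeasibleAllocation",
    "prob_affected",
    "build_b_matrix",
    "adjust_for_recessives",
    "sequential_allocate",
    "assign_matings",
]


class InfeasibleAllocation(RuntimeError):
    """Raised when some cow cannot be assigned any bull under the cap."""


@dataclass
class MatingPlan:
    """Result of one year's mate allocation.

    ``pair_f``/``pair_sum_paa``/``pair_made`` record every *evaluated*
    bull×cow pair (portfolio schemes evaluate the full herd matrix; random
    and truncation record only the matings made), supporting downstream
    diagnostics of inbreeding versus recessive load.
    """

    scheme: str
    cow_ids: np.ndarray  # one entry per mated cow
    bull_ids: np.ndarray  # assigned bull per cow (aligned with cow_ids)
    b_values: np.ndarray  # B (or B′) of each assigned mating
    f_ij: np.ndarray  # prospective-calf inbreeding per mating
    sum_paa: np.ndarray  # Σ_r P(aa)_r per mating
    penalty: np.ndarray  # Σ_r P(aa)_r·v_r per mating
    matings_used: dict[int, int] = field(default_factory=dict)
    # every evaluated pair (portfolio schemes only)
    pair_bull: np.ndarray | None = None
    pair_cow: np.ndarray | None = None
    pair_f: np.ndarray | None = None
    pair_sum_paa: np.ndarray | None = None
    pair_made: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.cow_ids)

    def validate(self, cap: int | None = None) -> None:
        if len(np.unique(self.cow_ids)) != len(self.cow_ids):
            raise AssertionError("a cow was assigned more than one bull")
        if cap is not None:
            for b, m in self.matings_used.items():
                if m > cap:
                    raise AssertionError(f"bull {b} exceeds mating cap: {m} > {cap}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cow_id": self.cow_ids,
                "bull_id": self.bull_ids,
                "b_value": self.b_values,
                "f_ij": self.f_ij,
                "sum_paa": self.sum_paa,
                "penalty": self.penalty,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def prob_affected(sire_genotype: int, dam_genotype: int) -> float:
    """P(homozygous-recessive calf) from parental minor-allele counts.

    Each parent transmits the minor allele with probability g/2; the calf is
    affected when it receives one from both, so carrier×carrier → ¼,
    affected×carrier → ½, affected×affected → 1.
    """
    for g in (sire_genotype, dam_genotype):
        if g not in (0, 1, 2):
            raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    return (sire_genotype / 2.0) * (dam_genotype / 2.0)


def _paa_matrices(
    g_bulls: np.ndarray, g_cows: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(Σ_r P(aa)_r, Σ_r P(aa)_r·v_r) for every bull×cow pair, vectorized.

    P(aa)_r = (g_bull/2)(g_cow/2) per locus, so the sums are scaled matrix
    products of the genotype matrices.
    """
    tb = g_bulls.astype(np.float64) / 2.0
    tc = g_cows.astype(np.float64) / 2.0
    sum_paa = tb @ tc.T
    penalty = (tb * values) @ tc.T
    return sum_paa, penalty


def build_b_matrix(
    bulls: np.ndarray,
    cows: np.ndarray,
    population: Population,
    kinship,
    lambda_inbreeding: float,
) -> np.ndarray:
    """Parent-average matrix penalized for prospective-calf inbreeding.

    ``kinship`` is any object with a ``matrix(bulls, cows)`` method returning
    F_ij; F is converted to percent before multiplying by λ ($ per 1 %).
    """
    if len(bulls) == 0 or len(cows) == 0:
        raise ValueError("bull and cow lists must be non-empty")
    if lambda_inbreeding < 0:
        raise ValueError("lambda_inbreeding must be >= 0")
    tbv_b = population.tbv[np.asarray(bulls) - 1]
    tbv_c = population.tbv[np.asarray(cows) - 1]
    f = kinship.matrix(bulls, cows)
    return 0.5 * (tbv_b[:, None] + tbv_c[None, :]) - lambda_inbreeding * (100.0 * f)


def adjust_for_recessives(
    b_matrix: np.ndarray,
    bulls: np.ndarray,
    cows: np.ndarray,
    population: Population,
    loci: tuple[RecessiveLocus, ...],
) -> np.ndarray:
    """B′ = B − Σ_r P(aa)_r·v_r applied elementwise."""
    if population.n_loci != len(loci):
        raise ValueError(
            f"locus-count mismatch: population has {population.n_loci}, got {len(loci)}"
        )
    if not loci:
        return b_matrix.copy()
    values = np.array([loc.value for loc in loci])
    g_b = population.genotypes[np.asarray(bulls) - 1]
    g_c = population.genotypes[np.asarray(cows) - 1]
    _, penalty = _paa_matrices(g_b, g_c, values)
    return b_matrix - penalty


def sequential_allocate(
    b_matrix: np.ndarray,
    bull_ids: np.ndarray,
    cow_ids: np.ndarray,
    cap: int | float,
    matings_used: dict[int, int] | None = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Greedy column-wise assignment of the published sequential rule.

    Cows (columns) are processed in ascending cow-id order; each receives the
    bull with the greatest B in her column among bulls below the cap, ties
    broken by lowest bull id. ``matings_used`` carries per-bull counts across
    calls so the cap holds globally when allocation is run herd by herd.

    Returns the assigned bull id per cow (in ``cow_ids`` order) and the
    updated counts.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    bull_ids = np.asarray(bull_ids)
    cow_ids = np.asarray(cow_ids)
    used = dict(matings_used) if matings_used is not None else {}
    counts = np.array([used.get(int(b), 0) for b in bull_ids], dtype=np.int64)

    # stable sort so equal-B ties resolve to the lowest bull id
    col_order = np.argsort(cow_ids, kind="stable")
    # per column, bull indices from highest B to lowest, id-stable:
    # sort by (-B, bull_id) via lexsort on pre-sorted-by-id rows
    id_order = np.argsort(bull_ids, kind="stable")
    b_sorted_rows = b_matrix[id_order]
    rank = np.argsort(-b_sorted_rows, axis=0, kind="stable")

    assignment = np.empty(len(cow_ids), dtype=np.int64)
    for j in col_order:
        chosen = -1
        for r in rank[:, j]:
            i = id_order[r]
            if counts[i] < cap:
                chosen = i
                break
        if chosen < 0:
            raise InfeasibleAllocation(
                f"cow {int(cow_ids[j])}: every bull has reached the cap of {cap}"
            )
        counts[chosen] += 1
        assignment[j] = bull_ids[chosen]

    for i, b in enumerate(bull_ids):
        if counts[i] > 0:
            used[int(b)] = int(counts[i])
    return assignment, used


# ---------------------------------------------------------------------------
# Scheme drivers
# ---------------------------------------------------------------------------

def _eligible(population: Population, scenario: Scenario) -> tuple[np.ndarray, np.ndarray]:
    bulls = population.live_ids(BULL)
    bulls = bulls[population.age(bulls) >= scenario.bull_min_breeding_age]
    cows = population.live_ids(COW)
    cows = cows[population.age(cows) >= scenario.cow_min_breeding_age]
    return bulls, cows


def _pair_stats(
    population: Population, bulls: np.ndarray, cows: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    g_b = population.genotypes[np.asarray(bulls) - 1]
    g_c = population.genotypes[np.asarray(cows) - 1]
    return _paa_matrices(g_b, g_c, values)


def _plan_from_assignment(
    scheme: str,
    population: Population,
    scenario: Scenario,
    cows: np.ndarray,
    assigned: np.ndarray,
    used: dict[int, int],
    b_values: np.ndarray | None = None,
) -> MatingPlan:
    kin = population.kinship
    f = np.array([kin.coancestry(b, c) for b, c in zip(assigned, cows)])
    values = scenario.value_array
    g_b = population.genotypes[assigned - 1].astype(np.float64) / 2.0
    g_c = population.genotypes[cows - 1].astype(np.float64) / 2.0
    sum_paa = (g_b * g_c).sum(axis=1)
    penalty = (g_b * g_c * values).sum(axis=1)
    if b_values is None:
        b_values = 0.5 * (
            population.tbv[assigned - 1] + population.tbv[cows - 1]
        ) - scenario.lambda_inbreeding * 100.0 * f
    return MatingPlan(
        scheme=scheme,
        cow_ids=cows,
        bull_ids=assigned,
        b_values=b_values,
        f_ij=f,
        sum_paa=sum_paa,
        penalty=penalty,
        matings_used=used,
    )


def _random_scheme(
    population: Population, scenario: Scenario, rng: np.random.Generator
) -> MatingPlan:
    bulls, cows = _eligible(population, scenario)
    cap = scenario.max_matings_per_bull
    if len(bulls) * cap < len(cows):
        raise InfeasibleAllocation(
            f"{len(cows)} cows exceed total capacity {len(bulls)} bulls × cap {cap}"
        )
    order = rng.permutation(len(cows))
    counts = np.zeros(len(bulls), dtype=np.int64)
    assigned = np.empty(len(cows), dtype=np.int64)
    open_idx = list(range(len(bulls)))
    for j in order:
        k = int(rng.integers(len(open_idx)))
        i = open_idx[k]
        assigned[j] = bulls[i]
        counts[i] += 1
        if counts[i] >= cap:
            open_idx.pop(k)
    used = {int(b): int(c) for b, c in zip(bulls, counts) if c > 0}
    return _plan_from_assignment("random", population, scenario, cows, assigned, used)


def _truncation_scheme(
    population: Population, scenario: Scenario, rng: np.random.Generator
) -> MatingPlan:
    bulls, cows = _eligible(population, scenario)
    n_keep = max(1, int(np.floor(scenario.trunc_fraction * len(bulls))))
    top = bulls[np.argsort(-population.tbv[bulls - 1], kind="stable")[:n_keep]]
    assigned = top[rng.integers(len(top), size=len(cows))]
    used: dict[int, int] = {}
    for b in assigned:
        used[int(b)] = used.get(int(b), 0) + 1
    return _plan_from_assignment("truncation", population, scenario, cows, assigned, used)


def _portfolio_scheme(
    population: Population,
    scenario: Scenario,
    rng: np.random.Generator,
    adjust: bool,
) -> MatingPlan:
    bulls, cows = _eligible(population, scenario)
    if len(bulls) == 0 or len(cows) == 0:
        raise InfeasibleAllocation("no eligible bulls or cows")
    cap = scenario.max_matings_per_bull
    values = scenario.value_array
    kin = population.kinship

    herd_of = population.herd[cows - 1]
    used: dict[int, int] = {}
    all_cows, all_assigned, all_b = [], [], []
    pair_bull, pair_cow, pair_f, pair_paa, pair_made = [], [], [], [], []

    for herd in np.unique(herd_of):
        herd_cows = np.sort(cows[herd_of == herd])
        # herd-specific sire portfolio: random 20 % sample of live bulls,
        # then the best n_herd_sires of the sample by TBV
        n_sample = min(len(bulls), int(np.ceil(scenario.herd_sample_fraction * len(bulls))))
        sample = rng.choice(bulls, size=n_sample, replace=False)
        n_sires = min(scenario.n_herd_sires, len(sample))
        sires = sample[np.argsort(-population.tbv[sample - 1], kind="stable")[:n_sires]]
        sires = np.sort(sires)

        b = build_b_matrix(sires, herd_cows, population, kin, scenario.lambda_inbreeding)
        sum_paa_m, penalty_m = _pair_stats(population, sires, herd_cows, values)
        if adjust:
            b = b - penalty_m
        assigned, used = sequential_allocate(b, sires, herd_cows, cap, used)

        sire_row = {int(s): i for i, s in enumerate(sires)}
        rows = np.array([sire_row[int(a)] for a in assigned])
        cols = np.arange(len(herd_cows))
        all_cows.append(herd_cows)
        all_assigned.append(assigned)
        all_b.append(b[rows, cols])

        f_m = kin.matrix(sires, herd_cows)
        made = np.zeros(b.shape, dtype=bool)
        made[rows, cols] = True
        pair_bull.append(np.broadcast_to(sires[:, None], b.shape).ravel())
        pair_cow.append(np.broadcast_to(herd_cows[None, :], b.shape).ravel())
        pair_f.append(f_m.ravel())
        pair_paa.append(sum_paa_m.ravel())
        pair_made.append(made.ravel())

    cows_cat = np.concatenate(all_cows)
    assigned_cat = np.concatenate(all_assigned)
    scheme = "modified_pryce" if adjust else "pryce"
    plan = _plan_from_assignment(
        scheme, population, scenario, cows_cat, assigned_cat, used,
        b_values=np.concatenate(all_b),
    )
    plan.pair_bull = np.concatenate(pair_bull)
    plan.pair_cow = np.concatenate(pair_cow)
    plan.pair_f = np.concatenate(pair_f)
    plan.pair_sum_paa = np.concatenate(pair_paa)
    plan.pair_made = np.concatenate(pair_made)
    return plan


def assign_matings(
    scheme: str,
    population: Population,
    scenario: Scenario,
    rng: np.random.Generator,
) -> MatingPlan:
    """Allocate one bull to every eligible cow under the named scheme.

    random — every eligible bull, cows assigned uniformly among bulls with
    remaining capacity (per-bull cap applies).
    truncation — the top ``trunc_fraction`` of bulls by TBV, random
    assignment, no cap.
    pryce — per-herd sire portfolios (random 20 % sample, top 50 by TBV),
    B-matrix allocation with the cap tracked globally across herds.
    modified_pryce — as pryce with the recessive-value adjustment B′.
    """
    if scheme == "random":
        return _random_scheme(population, scenario, rng)
    if scheme == "truncation":
        return _truncation_scheme(population, scenario, rng)
    if scheme in ("pryce", "modified_pryce"):
        return _portfolio_scheme(population, scenario, rng, adjust=(scheme == "modified_pryce"))
    raise ValueError(f"unknown scheme {scheme!r}")
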