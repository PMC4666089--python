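"""Small deterministic populations and pedigrees with known ground truth.

These generators exist so that every other module can be exercised in
milliseconds against closed-form expectations: toy pedigrees whose
inbreeding coefficients follow from Wright's path counting, fully specified
mini-populations for the mating schemes, and random valid pedigrees for
oracle-equivalence testing of the kinship code. Nothing here is checked in
as data — fixtures are built programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree
from .population import BULL, COW, Population
from .scenarios import RecessiveLocus, Scenario

__all__ = ["ToyPedigree", "toy_pedigrees", "toy_population", "random_pedigree"]


@dataclass(frozen=True)
class ToyPedigree:
    """A named hand-built pedigree with closed-form expectations.

    ``expected_inbreeding`` maps animal id → F from path counting;
    ``expected_coancestry`` maps (id, id) → kinship.
    """

    name: str
    pedigree: Pedigree
    expected_inbreeding: dict[int, float] = field(default_factory=dict)
    expected_coancestry: dict[tuple[int, int], float] = field(default_factory=dict)


def toy_pedigrees() -> list[ToyPedigree]:
    """Standard textbook pedigrees with their known coefficients."""
    out = []

    # two unrelated founders
    out.append(
        ToyPedigree(
            "founders",
            Pedigree({1: (0, 0), 2: (0, 0)}),
            expected_inbreeding={1: 0.0, 2: 0.0},
            expected_coancestry={(1, 2): 0.0, (1, 1): 0.5},
        )
    )

    # full sibs 3, 4 from founders 1 × 2; their calf 5 has F = 1/4
    out.append(
        ToyPedigree(
            "full_sib_mating",
            Pedigree({1: (0, 0), 2: (0, 0), 3: (1, 2), 4: (1, 2), 5: (3, 4)}),
            expected_inbreeding={3: 0.0, 4: 0.0, 5: 0.25},
            expected_coancestry={(3, 4): 0.25, (1, 3): 0.25},
        )
    )

    # half sibs 4, 5 share sire 1; their calf 6 has F = 1/8
    out.append(
        ToyPedigree(
            "half_sib_mating",
            Pedigree({1: (0, 0), 2: (0, 0), 3: (0, 0), 4: (1, 2), 5: (1, 3), 6: (4, 5)}),
            expected_inbreeding={6: 0.125},
            expected_coancestry={(4, 5): 0.125},
        )
    )

    # sire 1 × his own daughter 3 → calf 4 with F = 1/4
    out.append(
        ToyPedigree(
            "sire_daughter",
            Pedigree({1: (0, 0), 2: (0, 0), 3: (1, 2), 4: (1, 3)}),
            expected_inbreeding={4: 0.25},
            expected_coancestry={(1, 3): 0.25},
        )
    )

    # repeated full-sib mating: 3,4 full sibs → 5,6 (F = 1/4, full sibs);
    # 5 × 6 → 7 with F = f(5,6) = ¼·[½(1+F₃) + 2·f(3,4) + ½(1+F₄)] = 0.375
    out.append(
        ToyPedigree(
            "full_sib_line",
            Pedigree(
                {1: (0, 0), 2: (0, 0), 3: (1, 2), 4: (1, 2), 5: (3, 4), 6: (3, 4), 7: (5, 6)}
            ),
            expected_inbreeding={5: 0.25, 6: 0.25, 7: 0.375},
            expected_coancestry={(5, 6): 0.375},
        )
    )

    # three-generation inbred line: 5 is a full-sib-mating calf (F = 1/4);
    # mated to his own outbred daughter 7 → calf 8 with
    # F = f(5,7) = ½·[½(1+F₅) + f(5,6)] = ½·(0.625 + 0) = 0.3125
    out.append(
        ToyPedigree(
            "inbred_sire_daughter",
            Pedigree(
                {1: (0, 0), 2: (0, 0), 3: (1, 2), 4: (1, 2), 5: (3, 4),
                 6: (0, 0), 7: (5, 6), 8: (5, 7)}
            ),
            expected_inbreeding={5: 0.25, 7: 0.0, 8: 0.3125},
            expected_coancestry={(5, 7): 0.3125},
        )
    )
    return out


def toy_population(
    n_bulls: int,
    n_cows: int,
    loci: tuple[RecessiveLocus, ...],
    genotype_spec,
    rng: np.random.Generator,
    n_herds: int = 1,
    tbv: np.ndarray | None = None,
    birth_year: int = -2,
) -> Population:
    """A fully specified founder mini-population.

    ``genotype_spec`` is either an explicit ``(n_bulls + n_cows, n_loci)``
    genotype array (bulls first) or a per-locus frequency array from which
    alleles are drawn. TBV default to N(0, 100²) draws; ``birth_year``
    defaults to −2 so every founder is immediately breeding-eligible.
    """
    n = n_bulls + n_cows
    pop = Population(len(loci), [loc.name for loc in loci])
    idx = pop._append(n)
    pop.sex[idx[:n_bulls]] = BULL
    pop.sex[idx[n_bulls:]] = COW
    pop.birth_year[idx] = birth_year
    pop.herd[idx[n_bulls:]] = np.arange(n_cows) % n_herds
    pop.tbv[idx] = rng.normal(0.0, 100.0, size=n) if tbv is None else np.asarray(tbv, float)
    spec = np.asarray(genotype_spec)
    if spec.shape == (n, len(loci)):
        pop.genotypes[idx] = spec.astype(np.int8)
    elif spec.shape == (len(loci),):
        pop.genotypes[idx] = (
            (rng.random((n, len(loci))) < spec).astype(np.int8)
            + (rng.random((n, len(loci))) < spec).astype(np.int8)
        )
    else:
        raise ValueError(
            f"genotype_spec shape {spec.shape} matches neither ({n}, {len(loci)}) "
            f"nor ({len(loci)},)"
        )
    pop.alive[idx] = True
    pop.kinship.add_founders(pop.ids())
    return pop


def random_pedigree(n: int, rng: np.random.Generator, founder_fraction: float = 0.3) -> Pedigree:
    """A random valid pedigree of ``n`` animals for oracle testing.

    Ids are assigned in topological (birth) order: each non-founder draws a
    sire and dam among earlier animals of the right sex. Sexes alternate
    among founders so parents of both sexes always exist.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    n_founders = max(2, int(round(founder_fraction * n)))
    sexes = np.empty(n, dtype=np.int8)
    sexes[:n_founders] = np.arange(n_founders) % 2
    parents: dict[int, tuple[int, int]] = {i + 1: (0, 0) for i in range(n_founders)}
    for i in range(n_founders, n):
        prev = np.arange(1, i + 1)
        males = prev[sexes[: i] == 1]
        females = prev[sexes[: i] == 0]
        sire = int(rng.choice(males))
        dam = int(rng.choice(females))
        parents[i + 1] = (sire, dam)
        sexes[i] = int(rng.integers(2))
    return Pedigree(parents)
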