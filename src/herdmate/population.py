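"""Animal registry and base-population construction.

The population is stored columnar (one numpy array per attribute, indexed by
``id − 1``) because the simulator's per-year work — genotype transmission,
culling ranks, frequency counts — is bulk arithmetic over whole cohorts.
:meth:`Population.animal` materializes a single :class:`Animal` view for
ad-hoc inspection and tests.

Base animals are founders: unrelated, non-inbred, with true breeding values
drawn from the stated normal distributions (cows N($0, $200²), bulls
N($300, $200²)) and genotypes drawn allele-wise at the scenario's initial
minor-allele frequencies (Hardy–Weinberg proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import LiveKinship, Pedigree
from .scenarios import Scenario

__all__ = [
    "Animal",
    "Population",
    "COW",
    "BULL",
    "DEATH_CAUSES",
    "build_base_population",
    "allele_frequencies",
]

COW, BULL = 0, 1
DEATH_CAUSES = ("none", "lethal_recessive", "age", "tbv_cull", "involuntary", "random_cull")
_CAUSE_CODE = {c: i for i, c in enumerate(DEATH_CAUSES)}

_CHUNK = 4096


@dataclass(frozen=True)
class Animal:
    """Read-only view of one animal."""

    id: int
    sex: str  # "bull" or "cow"
    birth_year: int
    herd: int  # -1 for bulls (herd is a cow/calf attribute)
    sire_id: int | None
    dam_id: int | None
    tbv: float
    genotypes: np.ndarray  # minor-allele count per locus, {0, 1, 2}
    f: float
    alive: bool
    death_cause: str


class Population:
    """Registry of all animals ever simulated, plus the live-kinship matrix.

    Ids are assigned 1, 2, … in creation order and never reused, so id order
    is also birth order — which the pedigree recursion relies on.
    """

    def __init__(self, n_loci: int, locus_names: list[str] | None = None):
        self.n_loci = n_loci
        self.locus_names = locus_names or [f"locus{i}" for i in range(n_loci)]
        n0 = _CHUNK
        self.sex = np.zeros(n0, dtype=np.int8)
        self.birth_year = np.zeros(n0, dtype=np.int32)
        self.herd = np.full(n0, -1, dtype=np.int32)
        self.sire = np.zeros(n0, dtype=np.int64)  # 0 = unknown
        self.dam = np.zeros(n0, dtype=np.int64)
        self.tbv = np.zeros(n0, dtype=np.float64)
        self.f = np.zeros(n0, dtype=np.float64)
        self.alive = np.zeros(n0, dtype=bool)
        self.death_cause = np.zeros(n0, dtype=np.int8)
        self.genotypes = np.zeros((n0, n_loci), dtype=np.int8)
        self.n = 0
        self.current_year = 0
        self.kinship = LiveKinship()

    # -- storage -----------------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = self.sex.shape[0]
        if need <= cap:
            return
        new_cap = max(need, cap + max(cap // 2, _CHUNK))
        for name in ("sex", "birth_year", "herd", "sire", "dam", "tbv", "f",
                     "alive", "death_cause"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            if name == "herd":
                new[:] = -1
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        g = np.zeros((new_cap, self.n_loci), dtype=np.int8)
        g[: self.n] = self.genotypes[: self.n]
        self.genotypes = g

    def _append(self, count: int) -> np.ndarray:
        """Reserve ``count`` new rows; returns their 0-based indices."""
        self._grow(self.n + count)
        idx = np.arange(self.n, self.n + count)
        self.n += count
        return idx

    # -- queries -----------------------------------------------------------

    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def live_ids(self, sex: int | None = None) -> np.ndarray:
        mask = self.alive[: self.n].copy()
        if sex is not None:
            mask &= self.sex[: self.n] == sex
        return np.nonzero(mask)[0] + 1

    def age(self, ids: np.ndarray, year: int | None = None) -> np.ndarray:
        year = self.current_year if year is None else year
        return year - self.birth_year[np.asarray(ids) - 1]

    def animal(self, animal_id: int) -> Animal:
        i = int(animal_id) - 1
        if not 0 <= i < self.n:
            raise KeyError(f"unknown animal id {animal_id}")
        return Animal(
            id=int(animal_id),
            sex="bull" if self.sex[i] == BULL else "cow",
            birth_year=int(self.birth_year[i]),
            herd=int(self.herd[i]),
            sire_id=int(self.sire[i]) or None,
            dam_id=int(self.dam[i]) or None,
            tbv=float(self.tbv[i]),
            genotypes=self.genotypes[i].copy(),
            f=float(self.f[i]),
            alive=bool(self.alive[i]),
            death_cause=DEATH_CAUSES[self.death_cause[i]],
        )

    def pedigree(self) -> Pedigree:
        """Export the sire–dam graph (for the recursive kinship path)."""
        ids = range(1, self.n + 1)
        return Pedigree(
            {i: (int(self.sire[i - 1]), int(self.dam[i - 1])) for i in ids},
            birth_year={i: int(self.birth_year[i - 1]) for i in ids},
        )

    def mark_dead(self, ids: np.ndarray, cause: str) -> None:
        idx = np.asarray(ids, dtype=np.int64) - 1
        self.alive[idx] = False
        self.death_cause[idx] = _CAUSE_CODE[cause]

    # -- snapshot I/O ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        n = self.n
        df = pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "sex": np.where(self.sex[:n] == BULL, "bull", "cow"),
                "birth_year": self.birth_year[:n],
                "herd": self.herd[:n],
                "sire_id": self.sire[:n],
                "dam_id": self.dam[:n],
                "tbv": self.tbv[:n],
                "f": self.f[:n],
                "alive": self.alive[:n],
                "death_cause": [DEATH_CAUSES[c] for c in self.death_cause[:n]],
            }
        )
        for j, name in enumerate(self.locus_names):
            df[f"g_{name}"] = self.genotypes[:n, j]
        return df

    def write_snapshot(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sample_genotypes(rng: np.random.Generator, n: int, maf: np.ndarray) -> np.ndarray:
    """Two independent allele draws per locus at the given frequencies."""
    return (
        (rng.random((n, maf.size)) < maf).astype(np.int8)
        + (rng.random((n, maf.size)) < maf).astype(np.int8)
    )


def build_base_population(scenario: Scenario, rng: np.random.Generator) -> Population:
    """Construct the founder herd described by the scenario.

    Cows are assigned to herds round-robin in creation order (herd sizes
    within ±1); bulls carry no herd. Base animals homozygous for a lethal
    allele are retained alive — lethality acts on calves at birth, and at
    realistic frequencies the expected number of such founders is negligible.
    """
    maf = scenario.maf_array
    pop = Population(len(scenario.loci), scenario.locus_names)

    nc, nb = scenario.n_base_cows, scenario.n_base_bulls
    ci = pop._append(nc)
    pop.sex[ci] = COW
    pop.tbv[ci] = rng.normal(0.0, scenario.genetic_sd, size=nc)
    pop.birth_year[ci] = rng.integers(-4, 1, size=nc)
    pop.herd[ci] = np.arange(nc) % scenario.n_herds
    pop.genotypes[ci] = _sample_genotypes(rng, nc, maf)
    pop.alive[ci] = True

    bi = pop._append(nb)
    pop.sex[bi] = BULL
    pop.tbv[bi] = rng.normal(scenario.bull_tbv_mean, scenario.genetic_sd, size=nb)
    pop.birth_year[bi] = rng.integers(-9, 1, size=nb)
    pop.genotypes[bi] = _sample_genotypes(rng, nb, maf)
    pop.alive[bi] = True

    pop.kinship.add_founders(pop.ids())
    pop.current_year = 0
    return pop


def allele_frequencies(population: Population, year: int | None = None) -> dict[str, float]:
    """Minor-allele frequency per locus among live animals.

    ``frequency = minor-allele count / (2 × live animals)``. ``year`` is a
    label only; the count always reflects the registry's current state.
    """
    live = population.alive[: population.n]
    n_live = int(live.sum())
    if n_live == 0:
        raise ValueError("no live animals")
    counts = population.genotypes[: population.n][live].sum(axis=0, dtype=np.int64)
    freqs = counts / (2.0 * n_live)
    return dict(zip(population.locus_names, freqs.tolist()))
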