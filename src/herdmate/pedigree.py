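"""Pedigree inbreeding and coancestry.

Two exact implementations of Wright/Malécot kinship over a sire–dam graph:

* :class:`KinshipCache` — memoized recursive coancestry evaluated on demand
  from an arbitrary :class:`Pedigree`. This is the reference path and the one
  used for ad-hoc queries and small problems.
* :class:`LiveKinship` — a dense kinship matrix over the currently live
  animals, extended one row per calf via the same recurrence
  ``f(calf, x) = ½·(f(sire, x) + f(dam, x))``. The simulator uses it because
  each year's mate allocation evaluates on the order of 10⁵ prospective
  pairs, which a per-pair recursion cannot sustain over a deep pedigree.

Both treat founders (animals with no recorded parents) as unrelated and
non-inbred, and evaluate the pedigree to full depth. ``F_ij``, the inbreeding
coefficient of the calf of bull *i* and cow *j*, equals the coancestry of
*i* and *j*.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Pedigree",
    "KinshipCache",
    "LiveKinship",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

UNKNOWN = 0  # parent id meaning "founder side"


class Pedigree:
    """Sire/dam links for a set of animals, keyed by positive integer id.

    Parent id 0 (or ``None``) denotes an unknown parent. ``birth_year`` is
    optional and only used to orient the kinship recursion (falling back to
    id order, which is valid whenever ids are assigned in birth order).
    """

    def __init__(
        self,
        parents: Mapping[int, tuple[int, int]],
        birth_year: Mapping[int, int] | None = None,
    ):
        self._parents: dict[int, tuple[int, int]] = {}
        for an, (s, d) in parents.items():
            an, s, d = int(an), int(s or 0), int(d or 0)
            if an <= 0:
                raise ValueError(f"animal ids must be positive, got {an}")
            self._parents[an] = (s, d)
        self._birth = dict(birth_year) if birth_year else {}
        for an, (s, d) in self._parents.items():
            for p in (s, d):
                if p != UNKNOWN and p not in self._parents:
                    raise ValueError(f"animal {an} has unknown parent id {p}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}  # 0 in-progress, 1 done

        def visit(a: int) -> None:
            stack = [(a, iter(p for p in self._parents[a] if p != UNKNOWN))]
            state[a] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise ValueError(f"pedigree contains a cycle through animal {p}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(q for q in self._parents[p] if q != UNKNOWN)))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

        for a in self._parents:
            if a not in state:
                visit(a)

    def __contains__(self, animal: int) -> bool:
        return int(animal) in self._parents

    def __len__(self) -> int:
        return len(self._parents)

    def ids(self) -> list[int]:
        return sorted(self._parents)

    def parents(self, animal: int) -> tuple[int, int]:
        try:
            return self._parents[int(animal)]
        except KeyError:
            raise KeyError(f"unknown animal id {animal}") from None

    def add(self, animal: int, sire: int, dam: int) -> None:
        """Append one animal; parents must already be registered (or 0)."""
        animal = int(animal)
        if animal in self._parents:
            raise ValueError(f"animal id {animal} already in pedigree")
        for p in (sire, dam):
            if p != UNKNOWN and p not in self._parents:
                raise ValueError(f"parent {p} of {animal} not in pedigree")
        self._parents[animal] = (int(sire or 0), int(dam or 0))

    def order_key(self, animal: int) -> tuple[int, int]:
        return (self._birth.get(animal, animal), animal)


class KinshipCache:
    """Memoized recursive coancestry over a :class:`Pedigree`.

    The cache is append-only with respect to the pedigree: adding new animals
    never changes existing coefficients, so cached values stay valid as the
    pedigree grows. Callers running long simulations may drop and rebuild the
    cache between years to bound memory.
    """

    def __init__(self, pedigree: Pedigree):
        self.pedigree = pedigree
        self._memo: dict[tuple[int, int], float] = {}

    def coancestry(self, a: int, b: int) -> float:
        """Kinship f(a, b): P(two random homologous alleles are IBD).

        Equals the inbreeding coefficient of a prospective calf of ``a``
        and ``b``.
        """
        a, b = int(a), int(b)
        ped = self.pedigree
        if a not in ped:
            raise KeyError(f"unknown animal id {a}")
        if b not in ped:
            raise KeyError(f"unknown animal id {b}")
        return self._f(a, b)

    def _f(self, a: int, b: int) -> float:
        # iterative post-order evaluation to avoid Python recursion limits
        ped = self.pedigree
        memo = self._memo
        stack: list[tuple[int, int]] = [self._key(a, b)]
        while stack:
            key = stack[-1]
            if key in memo:
                stack.pop()
                continue
            x, y = key
            if x == y:
                s, d = ped.parents(x)
                if s == UNKNOWN or d == UNKNOWN:
                    memo[key] = 0.5
                    stack.pop()
                    continue
                sub = self._key(s, d)
                if sub in memo:
                    memo[key] = 0.5 * (1.0 + memo[sub])
                    stack.pop()
                else:
                    stack.append(sub)
                continue
            # recurse through the parents of the younger of the pair
            if ped.order_key(x) > ped.order_key(y):
                young, old = x, y
            else:
                young, old = y, x
            s, d = ped.parents(young)
            if s == UNKNOWN and d == UNKNOWN:
                memo[key] = 0.0
                stack.pop()
                continue
            subs = [self._key(p, old) for p in (s, d) if p != UNKNOWN]
            missing = [k for k in subs if k not in memo]
            if missing:
                stack.extend(missing)
            else:
                memo[key] = 0.5 * sum(memo[k] for k in subs)
                stack.pop()
        return memo[self._key(a, b)]

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    def inbreeding(self, x: int) -> float:
        """F(x) = coancestry of x's parents; 0 for founders."""
        s, d = self.pedigree.parents(x)
        if s == UNKNOWN or d == UNKNOWN:
            return 0.0
        return self._f(s, d)

    def matrix(self, bulls: Sequence[int], cows: Sequence[int]) -> np.ndarray:
        """Prospective-calf inbreeding F_ij for every bull×cow pair."""
        out = np.empty((len(bulls), len(cows)))
        for i, b in enumerate(bulls):
            for j, c in enumerate(cows):
                out[i, j] = self.coancestry(b, c)
        return out

    def clear(self) -> None:
        self._memo.clear()


def prospective_inbreeding_matrix(
    kinship, bulls: Sequence[int], cows: Sequence[int]
) -> np.ndarray:
    """F_ij matrix for prospective matings (delegates to the kinship object)."""
    return kinship.matrix(bulls, cows)


class LiveKinship:
    """Dense kinship matrix over a dynamic set of animals.

    Rows/columns are slots; ``id → slot`` is tracked internally. Founders are
    registered mutually unrelated with self-kinship ½. A calf row is the
    average of its parents' rows, and its self-kinship is
    ``½·(1 + f(sire, dam))``; both parents must still be registered when the
    calf is added (always true in the simulator: parents are alive at
    mating). :meth:`compact` drops animals that can no longer be parents.

    Stored as float32: kinship coefficients are dyadic rationals of the
    pedigree depth, and 24 bits of mantissa are ample for 20 generations
    while halving memory (the matrix is the simulator's dominant allocation).
    """

    def __init__(self, capacity: int = 1024):
        self._k = np.zeros((capacity, capacity), dtype=np.float32)
        self._slot: dict[int, int] = {}
        self._n = 0

    def __contains__(self, animal: int) -> bool:
        return int(animal) in self._slot

    def __len__(self) -> int:
        return self._n

    def _grow(self, need: int) -> None:
        cap = self._k.shape[0]
        if need <= cap:
            return
        new_cap = max(need, int(cap * 1.5) + 1)
        k = np.zeros((new_cap, new_cap), dtype=np.float32)
        k[: self._n, : self._n] = self._k[: self._n, : self._n]
        self._k = k

    def add_founders(self, ids: Iterable[int]) -> None:
        ids = [int(i) for i in ids]
        self._grow(self._n + len(ids))
        for an in ids:
            if an in self._slot:
                raise ValueError(f"animal {an} already registered")
            s = self._n
            self._slot[an] = s
            self._k[s, s] = 0.5
            self._n += 1

    def add_offspring(self, animal: int, sire: int, dam: int) -> float:
        """Register a calf; returns its inbreeding coefficient F."""
        animal = int(animal)
        if animal in self._slot:
            raise ValueError(f"animal {animal} already registered")
        si, di = self._slot[int(sire)], self._slot[int(dam)]
        self._grow(self._n + 1)
        n, k = self._n, self._k
        row = 0.5 * (k[si, :n] + k[di, :n])
        k[n, :n] = row
        k[:n, n] = row
        f = float(k[si, di])
        k[n, n] = 0.5 * (1.0 + f)
        self._slot[animal] = n
        self._n += 1
        return f

    def coancestry(self, a: int, b: int) -> float:
        return float(self._k[self._slot[int(a)], self._slot[int(b)]])

    def inbreeding(self, x: int) -> float:
        return 2.0 * float(self._k[self._slot[int(x)], self._slot[int(x)]]) - 1.0

    def matrix(self, bulls: Sequence[int], cows: Sequence[int]) -> np.ndarray:
        bi = np.fromiter((self._slot[int(b)] for b in bulls), dtype=np.intp, count=len(bulls))
        ci = np.fromiter((self._slot[int(c)] for c in cows), dtype=np.intp, count=len(cows))
        return self._k[np.ix_(bi, ci)].astype(float)

    def compact(self, keep: Iterable[int]) -> None:
        """Retain only ``keep`` (ids), releasing rows of culled animals."""
        keep = [int(a) for a in keep if int(a) in self._slot]
        idx = np.fromiter((self._slot[a] for a in keep), dtype=np.intp, count=len(keep))
        self._k[: len(keep), : len(keep)] = self._k[np.ix_(idx, idx)]
        self._slot = {a: i for i, a in enumerate(keep)}
        self._n = len(keep)


# ---------------------------------------------------------------------------
# CSV dialect: id,sire_id,dam_id with 0/empty = unknown, 1-based ids
# ---------------------------------------------------------------------------

def read_pedigree_csv(path: str | Path) -> Pedigree:
    parents: dict[int, tuple[int, int]] = {}
    with Path(path).open(newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["id", "sire_id", "dam_id"]:
            raise ValueError(f"{path}: expected header id,sire_id,dam_id")
        for i, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                an = int(row[0])
                s = int(row[1]) if row[1].strip() else 0
                d = int(row[2]) if row[2].strip() else 0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {i}: {row}") from exc
            parents[an] = (s, d)
    return Pedigree(parents)


def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "sire_id", "dam_id"])
        for an in pedigree.ids():
            s, d = pedigree.parents(an)
            writer.writerow([an, s, d])
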