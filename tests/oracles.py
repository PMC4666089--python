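"""Independent reference implementations used only to check production code.

These deliberately use different algorithms from the package: the tabular
(numerator-relationship-matrix) method for kinship, and a literal
re-transcription of the greedy column rule for allocation.
"""

import numpy as np

from herdmate.pedigree import Pedigree


def numerator_relationship_matrix(pedigree: Pedigree) -> tuple[np.ndarray, dict]:
    """Henderson's tabular method: A[i,j] over all animals, oldest first.

    Returns (A, id→index map). Coancestry f(a,b) = A[a,b]/2 and inbreeding
    F(x) = A[x,x] − 1.
    """
    ids = sorted(pedigree.ids(), key=pedigree.order_key)
    index = {an: i for i, an in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for i, an in enumerate(ids):
        s, d = pedigree.parents(an)
        si = index.get(s, -1)
        di = index.get(d, -1)
        a_sd = a[si, di] if (si >= 0 and di >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * a[si, j]
            if di >= 0:
                val += 0.5 * a[di, j]
            a[i, j] = a[j, i] = val
    return a, index


def greedy_allocation_reference(
    b: np.ndarray, bull_ids: np.ndarray, cow_ids: np.ndarray, cap: int
) -> np.ndarray:
    """Literal restatement of the sequential rule, one pair at a time.

    Cows in ascending-id order; each takes the under-cap bull with the
    highest B, ties to the lowest bull id. Returns assigned bull per cow in
    the original ``cow_ids`` order; NaN-free input assumed.
    """
    bull_ids = np.asarray(bull_ids)
    cow_ids = np.asarray(cow_ids)
    used = {int(bid): 0 for bid in bull_ids}
    out = np.empty(len(cow_ids), dtype=np.int64)
    for j in np.argsort(cow_ids, kind="stable"):
        best_bull, best_val = None, None
        for i in range(len(bull_ids)):
            bid = int(bull_ids[i])
            if used[bid] >= cap:
                continue
            v = b[i, j]
            if (
                best_val is None
                or v > best_val
                or (v == best_val and bid < best_bull)
            ):
                best_bull, best_val = bid, v
        if best_bull is None:
            raise RuntimeError("infeasible")
        used[best_bull] += 1
        out[j] = best_bull
    return out
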