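"""Brute-force reference implementations, used only by the test suite.

Exact computations are feasible only at toy scale: the median permutation
under summed edit distance by enumerating all m! candidate orderings, and
the best +-1 local alignment by enumerating all substring pairs and scoring
each with a full Needleman-Wunsch.  Both are deliberately independent of
the production code paths they check.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np

from .blocks import CorePermutation
from .errors import ConfigError

__all__ = ["batch_edit_distances", "exact_median", "exhaustive_local_align"]


def batch_edit_distances(candidates: np.ndarray, target: Sequence[int]) -> np.ndarray:
    """Edit distance of each row of ``candidates`` (K x m) to ``target``.

    Vectorizes the DP across candidates; the left-gap dependency within a
    row is resolved with a prefix-minimum scan.
    """
    cands = np.asarray(candidates, dtype=np.int64)
    k, m = cands.shape
    idx = np.arange(m + 1)
    prev = np.broadcast_to(idx, (k, m + 1)).copy()
    for i, x in enumerate(target, 1):
        sub = prev[:, :-1] + (cands != x)
        ins = prev[:, 1:] + 1
        row = np.minimum(sub, ins)
        full = np.concatenate([np.full((k, 1), i, dtype=np.int64), row], axis=1)
        full = np.minimum.accumulate(full - idx, axis=1) + idx
        prev = full
    return prev[:, -1]


def _symbols(perms: Sequence[CorePermutation | Sequence[int]]) -> list[list[int]]:
    out = []
    for p in perms:
        ids = p.signed_ids if isinstance(p, CorePermutation) else p
        out.append([abs(x) for x in ids])
    return out


def exact_median(
    perms: Sequence[CorePermutation | Sequence[int]], max_m: int = 8
) -> tuple[tuple[int, ...], int]:
    """Exact median permutation by exhaustive enumeration.

    Candidates range over permutations of the symbol set (the consensus is
    an ordering, not an arbitrary string).  Returns the lexicographically
    smallest minimizer and its summed unsigned edit distance.
    """
    seqs = _symbols(perms)
    symbols = sorted({s for seq in seqs for s in seq})
    m = len(symbols)
    if m == 0:
        return (), 0
    if m > max_m:
        raise ConfigError(f"exact median infeasible for m={m} > {max_m}")
    cands = np.array(list(permutations(symbols)), dtype=np.int64)  # lexicographic
    costs = np.zeros(len(cands), dtype=np.int64)
    for seq in seqs:
        costs += batch_edit_distances(cands, seq)
    best = int(np.argmin(costs))  # first minimum = lexicographically smallest
    return tuple(int(x) for x in cands[best]), int(costs[best])


def _nw_score(a: Sequence[int], b: Sequence[int]) -> int:
    """Global alignment score with match +1, mismatch -1, gap -1."""
    la, lb = len(a), len(b)
    prev = [-j for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [-i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = max(
                prev[j - 1] + (1 if ai == b[j - 1] else -1),
                prev[j] - 1,
                cur[j - 1] - 1,
            )
        prev = cur
    return prev[lb]


def exhaustive_local_align(a: Sequence[int], b: Sequence[int]) -> int:
    """Best +-1 local alignment score by enumerating all substring pairs.

    The empty alignment scores 0, so the result is never negative.
    """
    la, lb = len(a), len(b)
    best = 0
    for i in range(la):
        for j in range(i + 1, la + 1):
            sub_a = a[i:j]
            for k in range(lb):
                for l in range(k + 1, lb + 1):
                    s = _nw_score(sub_a, b[k:l])
                    if s > best:
                        best = s
    return best
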