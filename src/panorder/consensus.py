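"""Greedy consensus ordering of core blocks.

Restricted to core blocks, each genome is a signed permutation sigma^i of
the C-block identifiers.  The consensus ordering sigma* is defined as the
permutation minimizing ``sum_i L(sigma^i, sigma*)`` with *L* the Levenshtein
(edit) distance — the median permutation of the set.  Computing the median
string under edit distance is NP-complete, so sigma* is approximated
greedily:

1. Count, over all genomes, how often each pair of core blocks is adjacent
   in the core-only projection (dispensable/unique blocks are transparent).
2. Seed a path at the lowest-numbered unplaced block, look at its top-3
   neighbor frequencies f1 >= f2 >= f3 and apply the case analysis
   (i) ``f1 >= f2 > f3``: extend on both sides (C1 <- seed -> C2), then keep
   extending the left end as far as possible, then the right end;
   (ii) ``f1 > f2 = f3``: extend with C1 only and continue from C1;
   (iii) ``f1 = f2 = f3``: the neighborhood is ambiguous — suspend the path.
   Neighbors already placed in the working set O are excluded *before*
   ranking, which guarantees progress.
3. Repeat until every core block sits in exactly one path.

The result is a set of paths that a later refinement stage orients, splits
at mis-joins, and orders into the final consensus.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .blocks import CorePermutation
from .errors import InvariantError

__all__ = [
    "NeighborTable",
    "Path",
    "PathSet",
    "build_neighbor_table",
    "greedy_extend",
    "build_pathset",
    "edit_distance",
    "sum_edit_distance",
]


@dataclass
class NeighborTable:
    """Adjacency statistics of core blocks across genomes.

    ``pooled[a][b]`` counts occurrences of blocks |a| and |b| being adjacent
    in any genome's core projection (left and right pooled).  ``oriented``
    counts signed, ordered adjacencies: ``oriented[(x, y)]`` is how often
    signed block x is immediately followed by signed block y reading a
    genome left to right; a genome traversed right-to-left contributes the
    mirror ``(-y, -x)`` with the same count, so orientation-consistent
    extension can read either end of a path.
    """

    pooled: dict[int, Counter] = field(default_factory=lambda: defaultdict(Counter))
    oriented: Counter = field(default_factory=Counter)
    n_genomes: int = 0

    def neighbors_ranked(self, block_id: int, excluded: set[int]) -> list[tuple[int, int]]:
        """Unplaced neighbors of |block_id| as (neighbor_id, count), most
        frequent first, ties to the lower id."""
        items = [
            (nb, c) for nb, c in self.pooled[block_id].items() if nb not in excluded
        ]
        items.sort(key=lambda kv: (-kv[1], kv[0]))
        return items

    @property
    def support_threshold(self) -> int:
        """Minimum number of witnessing genomes to commit an adjacency:
        half the genomes (rounded up).  An adjacency attested only by a
        minority (e.g. the one genome carrying an inversion) must not steer
        the consensus."""
        return max(1, (self.n_genomes + 1) // 2)


@dataclass
class Path:
    """One linear ordering of signed core block ids."""

    signed_ids: list[int]
    status: str = "open"  # open | suspended | finalized
    seed: int = -1

    def __len__(self) -> int:
        return len(self.signed_ids)

    @property
    def block_ids(self) -> list[int]:
        return [abs(x) for x in self.signed_ids]

    def reversed_copy(self) -> "Path":
        return Path(
            signed_ids=[-x for x in reversed(self.signed_ids)],
            status=self.status,
            seed=self.seed,
        )


@dataclass
class PathSet:
    """The working set O of candidate consensus paths."""

    paths: list[Path] = field(default_factory=list)
    assigned: set[int] = field(default_factory=set)

    def add(self, path: Path) -> None:
        overlap = set(path.block_ids) & self.assigned
        if overlap:
            raise InvariantError(f"blocks {sorted(overlap)} already assigned")
        self.paths.append(path)
        self.assigned.update(path.block_ids)


def build_neighbor_table(perms: Sequence[CorePermutation]) -> NeighborTable:
    """Tally signed adjacencies over all genomes' core projections.

    Adjacency is counted within each permutation only (i.e. per genome and
    per chromosome group); permutation ends contribute single-sided counts.
    """
    table = NeighborTable()
    table.n_genomes = len({p.genome_id for p in perms})
    for perm in perms:
        ids = perm.signed_ids
        for x, y in zip(ids, ids[1:]):
            table.pooled[abs(x)][abs(y)] += 1
            table.pooled[abs(y)][abs(x)] += 1
            table.oriented[(x, y)] += 1
            table.oriented[(-y, -x)] += 1
        for x in ids:
            table.pooled.setdefault(abs(x), Counter())
    return table


def _top3_frequencies(cands: list[tuple[int, int]]) -> tuple[int, int, int]:
    f = [c for _, c in cands[:3]] + [0, 0, 0]
    return f[0], f[1], f[2]


def _signed_for_side(
    table: NeighborTable, terminus: int, neighbor_id: int, side: str
) -> int | None:
    """Sign of ``neighbor_id`` when placed on ``side`` of the path whose
    (signed) terminus is ``terminus``, by majority of observed oriented
    adjacencies; ties prefer the forward sign.

    Returns None when fewer than half the genomes witness the adjacency in
    this reading frame — e.g. when the neighbor's adjacency to the terminus
    is attested only by the genome carrying an inversion, or lies on the
    already-occupied side.  Committing such minority adjacencies is what
    drags a greedy consensus away from the median.
    """
    if side == "right":
        pos = table.oriented[(terminus, neighbor_id)]
        neg = table.oriented[(terminus, -neighbor_id)]
    else:
        pos = table.oriented[(neighbor_id, terminus)]
        neg = table.oriented[(-neighbor_id, terminus)]
    if pos + neg < table.support_threshold:
        return None
    return neighbor_id if pos >= neg else -neighbor_id


def _extend_end(path: Path, table: NeighborTable, assigned: set[int], side: str) -> None:
    """Extend one end of ``path`` as far as the case analysis allows.

    Per-step: no candidate -> stop (end exhausted); three or more candidates
    all at equal frequency (case iii) -> stop and mark the path suspended;
    top candidate unplaceable in this reading frame -> stop; otherwise
    append the top candidate C1 (cases i/ii coincide when only one side is
    free) with its majority-vote sign.
    """
    while True:
        terminus = path.signed_ids[0] if side == "left" else path.signed_ids[-1]
        cands = table.neighbors_ranked(abs(terminus), assigned)
        if not cands:
            return
        f1, f2, f3 = _top3_frequencies(cands)
        if len(cands) >= 3 and f1 == f2 == f3:
            path.status = "suspended"
            return
        nb = cands[0][0]
        signed = _signed_for_side(table, terminus, nb, side)
        if signed is None:
            return
        if side == "left":
            path.signed_ids.insert(0, signed)
        else:
            path.signed_ids.append(signed)
        assigned.add(nb)


def _best_side(
    table: NeighborTable, seed_signed: int, neighbor_id: int
) -> tuple[str, int] | None:
    """Pick (side, signed id) for a seed neighbor by the most frequently
    observed oriented adjacency; ties prefer the left side, then forward
    sign.  None when no placement reaches the witness threshold."""
    pooled_left = (
        table.oriented[(neighbor_id, seed_signed)]
        + table.oriented[(-neighbor_id, seed_signed)]
    )
    pooled_right = (
        table.oriented[(seed_signed, neighbor_id)]
        + table.oriented[(seed_signed, -neighbor_id)]
    )
    if max(pooled_left, pooled_right) < table.support_threshold:
        return None
    options = [
        ("left", neighbor_id, table.oriented[(neighbor_id, seed_signed)]),
        ("left", -neighbor_id, table.oriented[(-neighbor_id, seed_signed)]),
        ("right", neighbor_id, table.oriented[(seed_signed, neighbor_id)]),
        ("right", -neighbor_id, table.oriented[(seed_signed, -neighbor_id)]),
    ]
    side, signed, _ = max(options, key=lambda o: (o[2], o[0] == "left", o[1] > 0))
    return side, signed


def greedy_extend(seed: int, table: NeighborTable, pathset: PathSet) -> Path:
    """Grow a new path from ``seed`` and add it to ``pathset``.

    The seed step applies the full three-way case analysis; afterwards the
    left end is extended as far as possible, then the right end.
    """
    if seed in pathset.assigned:
        raise InvariantError(f"seed block {seed} already assigned")
    assigned = pathset.assigned
    assigned.add(seed)
    path = Path(signed_ids=[seed], seed=seed)
    cands = table.neighbors_ranked(seed, assigned)
    if cands:
        f1, f2, f3 = _top3_frequencies(cands)
        if len(cands) >= 3 and f1 == f2 == f3:
            path.status = "suspended"
        elif f2 > f3:
            # case (i): both top candidates flank the seed; C2 is skipped
            # (demoting to case ii) if no genome supports it on the free side
            c1, c2 = cands[0][0], cands[1][0]
            placed1 = _best_side(table, seed, c1)
            if placed1 is not None:
                side1, signed1 = placed1
                if side1 == "left":
                    path.signed_ids.insert(0, signed1)
                else:
                    path.signed_ids.append(signed1)
                assigned.add(c1)
                side2 = "right" if side1 == "left" else "left"
                terminus = path.signed_ids[0] if side2 == "left" else path.signed_ids[-1]
                signed2 = _signed_for_side(table, terminus, c2, side2)
                if signed2 is not None:
                    if side2 == "left":
                        path.signed_ids.insert(0, signed2)
                    else:
                        path.signed_ids.append(signed2)
                    assigned.add(c2)
        else:
            # case (ii): f1 > f2 = f3 — append C1 only, continue from it
            c1 = cands[0][0]
            placed1 = _best_side(table, seed, c1)
            if placed1 is not None:
                side1, signed1 = placed1
                if side1 == "left":
                    path.signed_ids.insert(0, signed1)
                else:
                    path.signed_ids.append(signed1)
                assigned.add(c1)
        if path.status != "suspended":
            _extend_end(path, table, assigned, "left")
        if path.status != "suspended":
            _extend_end(path, table, assigned, "right")
    pathset.paths.append(path)
    return path


def build_pathset(
    perms: Sequence[CorePermutation], table: NeighborTable | None = None
) -> PathSet:
    """Cover all core blocks with greedy paths.

    Seeds are taken at the lowest-numbered unplaced block so the result is
    deterministic for a given input.
    """
    if table is None:
        table = build_neighbor_table(perms)
    universe = sorted({abs(x) for p in perms for x in p.signed_ids})
    pathset = PathSet()
    for block_id in universe:
        if block_id not in pathset.assigned:
            greedy_extend(block_id, table, pathset)
    return pathset


def edit_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Unit-cost Levenshtein distance between two symbol sequences."""
    if len(a) == 0:
        return len(b)
    if len(b) == 0:
        return len(a)
    bn = np.asarray(b, dtype=np.int64)
    m = len(b)
    idx = np.arange(m + 1)
    prev = idx.copy()
    for i, x in enumerate(a, 1):
        row = np.minimum(prev[:-1] + (bn != x), prev[1:] + 1)
        full = np.concatenate(([i], row))
        # resolve the left-gap dependency in one vectorized prefix scan
        full = np.minimum.accumulate(full - idx) + idx
        prev = full
    return int(prev[-1])


def sum_edit_distance(
    ordering: Sequence[int],
    perms: Iterable[CorePermutation],
    signed: bool = False,
) -> int:
    """Summed edit distance of a proposed ordering to all genome permutations.

    By default symbols are compared unsigned (orientation ignored), matching
    the unsigned median-permutation objective; ``signed=True`` compares
    signed symbols instead.
    """
    total = 0
    for perm in perms:
        if signed:
            a, b = list(ordering), list(perm.signed_ids)
        else:
            a = [abs(x) for x in ordering]
            b = [abs(x) for x in perm.signed_ids]
        total += edit_distance(a, b)
    return total


def dump_debug_tsv(table: NeighborTable, pathset: PathSet, outdir) -> None:
    """Inspection dumps: pooled neighbor counts and the current path set."""
    from pathlib import Path as FsPath

    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "neighbors.tsv", "w") as fh:
        fh.write("block\tneighbor\tcount\n")
        for block in sorted(table.pooled):
            for nb, c in sorted(table.pooled[block].items()):
                fh.write(f"{block}\t{nb}\t{c}\n")
    with open(outdir / "paths.tsv", "w") as fh:
        fh.write("path\tstatus\tseed\tsigned_ids\n")
        for i, p in enumerate(pathset.paths):
            ids = ",".join(str(x) for x in p.signed_ids)
            fh.write(f"{i}\t{p.status}\t{p.seed}\t{ids}\n")
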