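"""Path orientation, mis-join splitting, and coordinate assignment.

Each greedy path is validated against the genomes it summarizes by local
alignment over block-ID symbols (match +1, mismatch -1, gap -1).  The
forward path and its reversal (order reversed, signs flipped) are both
aligned against every genome's core permutation; the orientation with the
higher summed best-local score wins.  If the summed score falls below a
threshold fraction (default 0.8) of the attainable maximum
``sum_g min(|path|, |perm_g|)``, the path is assumed to contain a mis-join:
it is cut at the boundaries of the best-aligned central span and the 1-3
nonempty pieces re-enter orientation/splitting until every piece passes.

Finally each surviving path is anchored at the median of its per-genome
best-alignment start coordinates (a majority vote robust to a minority of
rearranged genomes), paths are ordered by anchor within each chromosome
group, and consensus bp coordinates are laid out cumulatively, each block
spanning its median per-genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

from .blocks import ClassifiedBlock, CorePermutation
from .consensus import Path
from .errors import ConfigError, InvariantError

__all__ = [
    "PathAlignment",
    "ConsensusBlock",
    "ConsensusOrdering",
    "local_align",
    "orient_path",
    "split_misjoins",
    "assign_coordinates",
]


@dataclass(frozen=True)
class PathAlignment:
    """Best local alignment of a path against one genome permutation."""

    genome_id: str
    seq_name: str
    score: int
    path_span: tuple[int, int]  # half-open indices into the path
    perm_span: tuple[int, int]  # half-open indices into the permutation
    orientation_used: str = "forward"


def local_align(
    path: Sequence[int], perm: CorePermutation, signed: bool = False
) -> PathAlignment:
    """Smith–Waterman over block-ID symbols with the +1/-1 scheme.

    Symbols compare unsigned by default (orientation is judged separately by
    the forward-vs-reversed contest).  Among equal-scoring alignments the one
    ending earliest (path index, then permutation index) is reported, with a
    diagonal-preferring traceback — a deterministic stand-in for the
    "leftmost, then shortest" convention.
    """
    if signed:
        a = list(path)
        b = list(perm.signed_ids)
    else:
        a = [abs(x) for x in path]
        b = [abs(x) for x in perm.signed_ids]
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return PathAlignment(perm.genome_id, perm.seq_name, 0, (0, 0), (0, 0))
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        row = H[i]
        up = H[i - 1]
        for j in range(1, lb + 1):
            s = up[j - 1] + (1 if ai == b[j - 1] else -1)
            s = max(s, up[j] - 1, row[j - 1] - 1, 0)
            row[j] = s
            if s > best:
                best, bi, bj = s, i, j
    if best == 0:
        return PathAlignment(perm.genome_id, perm.seq_name, 0, (0, 0), (0, 0))
    # traceback to the start of the optimal local alignment
    i, j = bi, bj
    while H[i][j] > 0:
        s = H[i][j]
        if i > 0 and j > 0 and s == H[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1):
            i, j = i - 1, j - 1
        elif i > 0 and s == H[i - 1][j] - 1:
            i -= 1
        elif j > 0 and s == H[i][j - 1] - 1:
            j -= 1
        else:  # pragma: no cover - defensive
            break
    return PathAlignment(perm.genome_id, perm.seq_name, best, (i, bi), (j, bj))


def _summed_score(path: Path, perms: Sequence[CorePermutation]) -> tuple[int, list[PathAlignment]]:
    aligns = [local_align(path.signed_ids, p) for p in perms]
    return sum(al.score for al in aligns), aligns


def orient_path(path: Path, perms: Sequence[CorePermutation]) -> Path:
    """Keep the orientation (forward vs reversed) with the higher summed
    best-local score; exact ties keep forward.  Idempotent."""
    if len(path) == 0:
        raise InvariantError("cannot orient an empty path")
    fwd_score, _ = _summed_score(path, perms)
    rev = path.reversed_copy()
    rev_score, _ = _summed_score(rev, perms)
    return rev if rev_score > fwd_score else path


def split_misjoins(
    path: Path,
    perms: Sequence[CorePermutation],
    threshold_frac: float = 0.8,
) -> list[Path]:
    """Orient, score, and recursively split a path at suspected mis-joins.

    A path passes when its summed best-local score reaches
    ``threshold_frac * sum_g min(|path|, |perm_g|)``.  A failing path is cut
    at the best-aligned central span into up to three pieces (left overhang,
    center, right overhang), each re-entering orientation and splitting.
    Paths of length <= 2 are finalized outright (no detectable mis-join under
    +-1 scoring), and a central span covering the whole path finalizes it,
    so recursion strictly shrinks and terminates.
    """
    if not (0 < threshold_frac <= 1):
        raise ConfigError(f"threshold_frac must be in (0, 1], got {threshold_frac}")

    def _refine(p: Path) -> list[Path]:
        if len(p) <= 2:
            p.status = "finalized"
            return [p]
        p = orient_path(p, perms)
        total, aligns = _summed_score(p, perms)
        max_possible = sum(min(len(p), len(perm)) for perm in perms)
        if max_possible == 0 or total >= threshold_frac * max_possible:
            p.status = "finalized"
            return [p]
        best = max(aligns, key=lambda al: al.score)
        s, e = best.path_span
        if (s, e) == (0, len(p)) or s == e:
            p.status = "finalized"
            return [p]
        pieces = [
            Path(signed_ids=list(p.signed_ids[a:b]), seed=p.seed)
            for a, b in ((0, s), (s, e), (e, len(p)))
            if b > a
        ]
        out: list[Path] = []
        for piece in pieces:
            out.extend(_refine(piece))
        return out

    return _refine(Path(signed_ids=list(path.signed_ids), seed=path.seed))


@dataclass(frozen=True)
class ConsensusBlock:
    block_id: int
    orientation: int  # +1 forward, -1 reversed, relative to the consensus
    start: int
    end: int
    group: str
    path_index: int


@dataclass
class ConsensusOrdering:
    """Final ordered, oriented, coordinate-assigned sequence of core blocks."""

    blocks: list[ConsensusBlock]
    paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        last = -1
        for cb in self.blocks:
            if cb.block_id in seen:
                raise InvariantError(f"block {cb.block_id} repeated in consensus")
            seen.add(cb.block_id)
            if cb.start < last:
                raise InvariantError("consensus coordinates must be increasing")
            last = cb.start
        self.rank = {cb.block_id: i for i, cb in enumerate(self.blocks)}
        self.orientation = {cb.block_id: cb.orientation for cb in self.blocks}
        self.interval = {cb.block_id: (cb.start, cb.end) for cb in self.blocks}
        self.group_of = {cb.block_id: cb.group for cb in self.blocks}

    @property
    def total_span(self) -> int:
        return self.blocks[-1].end if self.blocks else 0


def assign_coordinates(
    paths_by_group: Mapping[str, Sequence[Path]],
    perms_by_group: Mapping[str, Sequence[CorePermutation]],
    classified: Sequence[ClassifiedBlock],
) -> ConsensusOrdering:
    """Anchor, order and lay out finalized paths into the consensus.

    Each path's anchor is the median over genomes of the bp start of its
    best local alignment; paths are sorted by anchor within their chromosome
    group, groups by name.  Consensus coordinates accumulate from 0, each
    block contributing its median per-genome interval length.
    """
    lengths = {cb.block_id: cb.median_length for cb in classified}
    # consensus orientation of each block = majority of genome strands;
    # path-internal signs can be arbitrary where adjacency evidence was
    # ambiguous (e.g. across a shuffled region), the vote is not
    strand_vote: dict[str, dict[int, int]] = {}
    for group, perms in perms_by_group.items():
        vote: dict[int, int] = {}
        for perm in perms:
            for signed in perm.signed_ids:
                vote[abs(signed)] = vote.get(abs(signed), 0) + (1 if signed >= 0 else -1)
        strand_vote[group] = vote
    blocks: list[ConsensusBlock] = []
    cursor = 0
    all_paths: list[Path] = []
    for group in sorted(paths_by_group):
        perms = perms_by_group[group]
        anchored: list[tuple[float, Path]] = []
        for path in paths_by_group[group]:
            if path.status != "finalized":
                raise InvariantError("assign_coordinates requires finalized paths")
            starts: list[int] = []
            for perm in perms:
                al = local_align(path.signed_ids, perm)
                if al.score > 0 and perm.starts:
                    starts.append(perm.starts[al.perm_span[0]])
            if not starts:
                raise InvariantError(
                    f"path seeded at {path.seed} aligns to no genome in group {group!r}"
                )
            anchored.append((float(median(starts)), path))
        anchored.sort(key=lambda t: (t[0], t[1].seed))
        for _, path in anchored:
            all_paths.append(path)
            pi = len(all_paths) - 1
            for signed in path.signed_ids:
                bid = abs(signed)
                length = lengths.get(bid)
                if length is None:
                    raise InvariantError(f"no classified block with id {bid}")
                vote = strand_vote[group].get(bid, 0)
                orientation = (1 if vote > 0 else -1) if vote else (1 if signed >= 0 else -1)
                blocks.append(
                    ConsensusBlock(
                        block_id=bid,
                        orientation=orientation,
                        start=cursor,
                        end=cursor + length,
                        group=group,
                        path_index=pi,
                    )
                )
                cursor += length
    return ConsensusOrdering(blocks=blocks, paths=all_paths)
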