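"""Core / dispensable / unique block classification.

A pan-genome over *n* individuals partitions its alignment blocks by
occupancy: a **core** (C) block occurs in all *n* genomes, a **unique** (U)
block in exactly one, and a **dispensable** (D, also "accessory") block in
between (2..n-1).  Unlike part of the literature, unique blocks are kept
distinct from dispensable ones here; a compatibility flag in the summary
merges them back.

After classification each genome is rewritten as an ordered sequence of
signed block occurrences, and the core-only projection of that sequence is a
signed permutation of the C-block identifiers — the object the consensus
ordering is computed from.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .alignment_io import AlignmentBlock, BlockInterval, GenomeMeta
from .errors import ConfigError, InvariantError

__all__ = [
    "BlockClass",
    "ClassifiedBlock",
    "BlockOccurrence",
    "GenomeBlockSequence",
    "CorePermutation",
    "classify_blocks",
    "genome_sequences",
    "core_permutations",
    "core_groups",
    "grouped_core_permutations",
    "core_fraction",
    "summary_table",
]


class BlockClass(Enum):
    CORE = "C"
    DISPENSABLE = "D"
    UNIQUE = "U"


@dataclass(frozen=True)
class ClassifiedBlock:
    block_id: int
    block_class: BlockClass
    class_label: str  # C<k>/D<k>/U<k>, serial per class
    intervals: tuple[BlockInterval, ...]

    def interval_for(self, genome_id: str) -> BlockInterval | None:
        for iv in self.intervals:
            if iv.genome_id == genome_id:
                return iv
        return None

    @property
    def median_length(self) -> int:
        lengths = sorted(iv.length for iv in self.intervals)
        return lengths[(len(lengths) - 1) // 2]


@dataclass(frozen=True)
class BlockOccurrence:
    block_id: int
    block_class: BlockClass
    class_label: str
    seq_name: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class GenomeBlockSequence:
    """One genome rewritten as its ordered sequence of block occurrences."""

    genome_id: str
    occurrences: tuple[BlockOccurrence, ...]

    def core_occurrences(self) -> tuple[BlockOccurrence, ...]:
        return tuple(o for o in self.occurrences if o.block_class is BlockClass.CORE)


@dataclass(frozen=True)
class CorePermutation:
    """Signed permutation of core block ids for one (genome, group).

    ``signed_ids[k]`` is ``+block_id`` for a forward occurrence and
    ``-block_id`` for a reverse one; ``starts[k]`` is the bp start of that
    occurrence in its own sequence (used for coordinate anchoring and
    dot-plots).
    """

    genome_id: str
    seq_name: str
    signed_ids: tuple[int, ...]
    starts: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.signed_ids)


def classify_blocks(blocks: Sequence[AlignmentBlock], n: int) -> list[ClassifiedBlock]:
    """Partition blocks into C/D/U by genome occupancy.

    Occupancy n -> CORE, 1 -> UNIQUE, 2..n-1 -> DISPENSABLE.  Class serial
    numbers are assigned in input order within each class, so labels are
    stable for a given block list.
    """
    if n < 2:
        raise ConfigError(f"need at least 2 genomes, got {n}")
    serial: Counter[BlockClass] = Counter()
    out: list[ClassifiedBlock] = []
    for block in blocks:
        k = len(block.intervals)
        if k < 1 or k > n:
            raise InvariantError(
                f"block {block.block_id}: {k} intervals with n={n} genomes"
            )
        if k == n:
            cls = BlockClass.CORE
        elif k == 1:
            cls = BlockClass.UNIQUE
        else:
            cls = BlockClass.DISPENSABLE
        serial[cls] += 1
        out.append(
            ClassifiedBlock(
                block_id=block.block_id,
                block_class=cls,
                class_label=f"{cls.value}{serial[cls]}",
                intervals=tuple(block.intervals),
            )
        )
    return out


def genome_sequences(
    classified: Sequence[ClassifiedBlock], catalog: Sequence[GenomeMeta]
) -> list[GenomeBlockSequence]:
    """Order every genome's block occurrences by (sequence, start).

    Raises if two blocks overlap on the same sequence of the same genome;
    the aligner's blocks must tile each genome disjointly.
    """
    per_genome: dict[str, list[BlockOccurrence]] = {g.genome_id: [] for g in catalog}
    for cb in classified:
        for iv in cb.intervals:
            if iv.genome_id not in per_genome:
                raise InvariantError(f"block {cb.block_id}: unknown genome {iv.genome_id!r}")
            per_genome[iv.genome_id].append(
                BlockOccurrence(
                    block_id=cb.block_id,
                    block_class=cb.block_class,
                    class_label=cb.class_label,
                    seq_name=iv.seq_name,
                    start=iv.start,
                    end=iv.end,
                    strand=iv.strand,
                )
            )
    seq_order = {
        g.genome_id: {s: i for i, s in enumerate(g.seq_names)} for g in catalog
    }
    out: list[GenomeBlockSequence] = []
    for g in catalog:
        occs = per_genome[g.genome_id]
        occs.sort(key=lambda o: (seq_order[g.genome_id].get(o.seq_name, 1 << 30), o.start))
        for a, b in zip(occs, occs[1:]):
            if a.seq_name == b.seq_name and b.start < a.end:
                raise InvariantError(
                    f"genome {g.genome_id!r}: blocks {a.block_id} and {b.block_id} "
                    f"overlap on {a.seq_name}"
                )
        if not occs:
            warnings.warn(f"genome {g.genome_id!r} absent from all blocks")
        out.append(GenomeBlockSequence(genome_id=g.genome_id, occurrences=tuple(occs)))
    return out


def core_permutations(seqs: Sequence[GenomeBlockSequence]) -> list[CorePermutation]:
    """Project each (genome, sequence) onto its signed core permutation."""
    out: list[CorePermutation] = []
    for gs in seqs:
        by_seq: dict[str, list[BlockOccurrence]] = defaultdict(list)
        for o in gs.core_occurrences():
            by_seq[o.seq_name].append(o)
        seen: set[int] = set()
        for seq_name, occs in by_seq.items():
            for o in occs:
                if o.block_id == 0:
                    raise InvariantError(
                        "core block ids must be >= 1 (0 has no sign in the "
                        "signed permutation representation)"
                    )
                if o.block_id in seen:
                    raise InvariantError(
                        f"core block {o.block_id} occurs twice in genome {gs.genome_id!r}"
                    )
                seen.add(o.block_id)
            out.append(
                CorePermutation(
                    genome_id=gs.genome_id,
                    seq_name=seq_name,
                    signed_ids=tuple(
                        o.block_id if o.strand == "+" else -o.block_id for o in occs
                    ),
                    starts=tuple(o.start for o in occs),
                )
            )
    return out


def core_groups(classified: Sequence[ClassifiedBlock]) -> dict[int, str]:
    """Assign each core block to a chromosome group.

    The group is the majority sequence name among the block's per-genome
    placements (lexicographically smallest on ties); a block a minority of
    genomes relocated to another chromosome still groups with the majority,
    and surfaces later as a translocation.
    """
    groups: dict[int, str] = {}
    for cb in classified:
        if cb.block_class is not BlockClass.CORE:
            continue
        counts = Counter(iv.seq_name for iv in cb.intervals)
        top = max(counts.values())
        groups[cb.block_id] = min(s for s, c in counts.items() if c == top)
    return groups


def grouped_core_permutations(
    seqs: Sequence[GenomeBlockSequence], groups: Mapping[int, str]
) -> dict[str, list[CorePermutation]]:
    """Per chromosome group, one signed core permutation per genome.

    A genome's permutation for group *g* lists the core blocks assigned to
    *g* in the order they occur along that genome (its sequences traversed
    in catalog order), wherever they physically sit.
    """
    out: dict[str, list[CorePermutation]] = {g: [] for g in sorted(set(groups.values()))}
    for gs in seqs:
        per_group: dict[str, list[BlockOccurrence]] = defaultdict(list)
        for o in gs.core_occurrences():
            if o.block_id == 0:
                raise InvariantError(
                    "core block ids must be >= 1 (0 has no sign in the "
                    "signed permutation representation)"
                )
            grp = groups.get(o.block_id)
            if grp is not None:
                per_group[grp].append(o)
        for grp in out:
            occs = per_group.get(grp, [])
            out[grp].append(
                CorePermutation(
                    genome_id=gs.genome_id,
                    seq_name=grp,
                    signed_ids=tuple(
                        o.block_id if o.strand == "+" else -o.block_id for o in occs
                    ),
                    starts=tuple(o.start for o in occs),
                )
            )
    return out


def core_fraction(
    classified: Sequence[ClassifiedBlock], catalog: Sequence[GenomeMeta]
) -> tuple[float, dict[str, float]]:
    """Fraction of the pan-genome covered by core blocks.

    Returns ``(overall, per_genome)``: overall is summed core bp across all
    genomes divided by summed genome lengths; per-genome fractions let either
    denominator convention be recovered.
    """
    core_bp: Counter[str] = Counter()
    for cb in classified:
        if cb.block_class is BlockClass.CORE:
            for iv in cb.intervals:
                core_bp[iv.genome_id] += iv.length
    per_genome: dict[str, float] = {}
    total_core = 0
    total_len = 0
    for g in catalog:
        if g.total_length <= 0:
            raise ConfigError(f"genome {g.genome_id!r}: missing sequence lengths")
        per_genome[g.genome_id] = core_bp[g.genome_id] / g.total_length
        total_core += core_bp[g.genome_id]
        total_len += g.total_length
    return total_core / total_len, per_genome


def summary_table(
    classified: Sequence[ClassifiedBlock],
    catalog: Sequence[GenomeMeta],
    merge_unique: bool = False,
) -> pd.DataFrame:
    """Per-class block count, cumulative bp and bp fraction.

    ``merge_unique=True`` folds U into D for compatibility with conventions
    where unique content is a special case of dispensable content.
    """
    total_len = sum(g.total_length for g in catalog)
    rows: dict[str, dict[str, float]] = {}
    for cb in classified:
        cls = cb.block_class
        if merge_unique and cls is BlockClass.UNIQUE:
            cls = BlockClass.DISPENSABLE
        row = rows.setdefault(cls.name.lower(), {"count": 0, "bp": 0})
        row["count"] += 1
        row["bp"] += sum(iv.length for iv in cb.intervals)
    df = pd.DataFrame(
        [
            {"class": name, "count": int(r["count"]), "bp": int(r["bp"]),
             "fraction": r["bp"] / total_len if total_len else 0.0}
            for name, r in sorted(rows.items())
        ]
    )
    return df
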