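"""Synthetic pan-genomes with known ground truth.

The generator emulates the coordinate-level output of a multiple
whole-genome aligner over *n* same-species assemblies: an ancestral
sequence of blocks is laid down, dispensable blocks are dropped from random
genome subsets, unique blocks are inserted per genome, and structural
events (inversions, translocations, shuffled "highly variable" regions) are
planted in chosen genomes.  Block coordinates are then assigned with small
random inter-block gaps, and the result can be serialized in the same
XMFA/backbone dialects the real pipeline consumes.

Everything is driven by one integer seed; a fixed seed reproduces the
fixture byte for byte.  The returned :class:`TruthTable` records the
planted classes, per-genome block orders/strands, the planted consensus
permutation and the event list — the oracle every downstream module is
tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import (
    AlignmentBlock,
    BlockInterval,
    GenomeMeta,
    dump_catalog,
    write_backbone,
    write_xmfa,
)
from .errors import ConfigError

__all__ = [
    "Inversion",
    "Translocation",
    "VariableRegion",
    "ScenarioConfig",
    "TruthTable",
    "SyntheticPanGenome",
    "generate",
    "preset_scenarios",
    "divergent_pair",
]


@dataclass(frozen=True)
class Inversion:
    """Reverse (order and strand) the segment spanning ``length`` core
    blocks starting at consensus rank ``start_rank`` in one genome.
    Dispensable/unique blocks inside the segment flip with it."""

    genome: int
    start_rank: int
    length: int


@dataclass(frozen=True)
class Translocation:
    """Move the core block at consensus rank ``source_rank`` in one genome
    to just after the core block at rank ``dest_rank`` (optionally onto a
    second chromosome ``dest_seq``)."""

    genome: int
    source_rank: int
    dest_rank: int
    dest_seq: str | None = None


@dataclass(frozen=True)
class VariableRegion:
    """Independently shuffle, in every genome, the blocks spanning
    ``length`` core ranks from ``start_rank`` — a region too variable for a
    consensus to extend across."""

    start_rank: int
    length: int


@dataclass(frozen=True)
class ScenarioConfig:
    n_genomes: int = 4
    n_core: int = 30
    n_dispensable: int = 10
    n_unique_per_genome: int = 4
    block_length_range: tuple[int, int] = (200, 1000)
    gap_range: tuple[int, int] = (0, 50)
    inversions: tuple[Inversion, ...] = ()
    translocations: tuple[Translocation, ...] = ()
    variable_regions: tuple[VariableRegion, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ConfigError("need at least 2 genomes")
        if self.n_core < 1:
            raise ConfigError("need at least 1 core block")
        if self.n_dispensable > 0 and self.n_genomes < 3:
            raise ConfigError("dispensable blocks require n >= 3 genomes")
        lo, hi = self.block_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid block_length_range")
        for ev in self.inversions:
            if not (0 <= ev.start_rank and ev.start_rank + ev.length <= self.n_core):
                raise ConfigError(f"inversion out of range: {ev}")
            if not (0 <= ev.genome < self.n_genomes):
                raise ConfigError(f"inversion targets unknown genome: {ev}")
        for ev in self.translocations:
            if not (0 <= ev.source_rank < self.n_core and 0 <= ev.dest_rank < self.n_core):
                raise ConfigError(f"translocation out of range: {ev}")
            if not (0 <= ev.genome < self.n_genomes):
                raise ConfigError(f"translocation targets unknown genome: {ev}")
        for ev in self.variable_regions:
            if not (0 <= ev.start_rank and ev.start_rank + ev.length <= self.n_core):
                raise ConfigError(f"variable region out of range: {ev}")


@dataclass
class _Occ:
    block_id: int
    cls: str  # C | D | U
    length: int
    strand: str
    seq: str = "chr1"


@dataclass
class TruthTable:
    """Ground truth for one synthetic scenario."""

    block_class: dict[int, str]  # block_id -> C | D | U
    block_length: dict[int, int]
    planted_consensus: tuple[int, ...]  # core block ids in ancestral order
    genome_orders: dict[str, tuple[tuple[int, str, str], ...]]  # gid -> ((block, strand, seq), ...)
    events: dict = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"C": 0, "D": 0, "U": 0}
        for cls in self.block_class.values():
            counts[cls] += 1
        return counts

    def core_bp(self) -> int:
        """Summed core bp over all genomes (every core block occurs once per genome)."""
        n = len(self.genome_orders)
        return n * sum(
            self.block_length[b] for b, c in self.block_class.items() if c == "C"
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("block_id\tclass\tlength\n")
            for bid in sorted(self.block_class):
                fh.write(f"{bid}\t{self.block_class[bid]}\t{self.block_length[bid]}\n")


@dataclass
class SyntheticPanGenome:
    config: ScenarioConfig
    catalog: list[GenomeMeta]
    alignment_blocks: list[AlignmentBlock]
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Serialize the fixture: XMFA, backbone table, catalog YAML, truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "xmfa": outdir / "alignment.xmfa",
            "backbone": outdir / "backbone.tsv",
            "catalog": outdir / "catalog.yaml",
            "truth": outdir / "truth.tsv",
        }
        write_xmfa(self.alignment_blocks, self.catalog, paths["xmfa"])
        write_backbone(self.alignment_blocks, self.catalog, paths["backbone"])
        dump_catalog(self.catalog, paths["catalog"])
        self.truth.to_tsv(paths["truth"])
        return paths


def _apply_events(
    occ_lists: list[list[_Occ]],
    core_ids: list[int],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> None:
    def core_positions(occs: list[_Occ]) -> dict[int, int]:
        return {o.block_id: i for i, o in enumerate(occs) if o.cls == "C"}

    for ev in config.variable_regions:
        span_ids = set(core_ids[ev.start_rank : ev.start_rank + ev.length])
        for occs in occ_lists:
            pos = [i for i, o in enumerate(occs) if o.cls == "C" and o.block_id in span_ids]
            if len(pos) < 2:
                continue
            i0, i1 = pos[0], pos[-1] + 1
            segment = occs[i0:i1]
            perm = rng.permutation(len(segment))
            occs[i0:i1] = [segment[k] for k in perm]
    for ev in config.inversions:
        occs = occ_lists[ev.genome]
        span_ids = set(core_ids[ev.start_rank : ev.start_rank + ev.length])
        pos = [i for i, o in enumerate(occs) if o.cls == "C" and o.block_id in span_ids]
        if not pos:
            continue
        i0, i1 = pos[0], pos[-1] + 1
        segment = occs[i0:i1][::-1]
        for o in segment:
            o.strand = "-" if o.strand == "+" else "+"
        occs[i0:i1] = segment
    for ev in config.translocations:
        occs = occ_lists[ev.genome]
        src_id = core_ids[ev.source_rank]
        dst_id = core_ids[ev.dest_rank]
        cp = core_positions(occs)
        moved = occs.pop(cp[src_id])
        if ev.dest_seq is not None:
            moved.seq = ev.dest_seq
            occs.append(moved)
        else:
            cp = core_positions(occs)
            occs.insert(cp[dst_id] + 1, moved)


def generate(config: ScenarioConfig) -> SyntheticPanGenome:
    """Build a synthetic pan-genome from a scenario description."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    lo, hi = config.block_length_range

    # ancestral order interleaves core and dispensable slots; ids follow
    # ancestral order (starting at 1 — the signed representation reserves
    # 0), so the planted consensus is the sorted core id list
    n_anc = config.n_core + config.n_dispensable
    kinds = np.array(["C"] * config.n_core + ["D"] * config.n_dispensable)
    rng.shuffle(kinds)
    lengths = rng.integers(lo, hi + 1, size=n_anc)
    block_class: dict[int, str] = {}
    block_length: dict[int, int] = {}
    core_ids: list[int] = []
    presence: dict[int, set[int]] = {}
    for bid, (kind, length) in enumerate(zip(kinds, lengths), start=1):
        block_class[bid] = str(kind)
        block_length[bid] = int(length)
        if kind == "C":
            core_ids.append(bid)
            presence[bid] = set(range(n))
        else:
            k = int(rng.integers(2, n))  # size in 2..n-1
            members = rng.choice(n, size=k, replace=False)
            presence[bid] = set(int(g) for g in members)

    occ_lists: list[list[_Occ]] = []
    next_id = n_anc + 1
    for g in range(n):
        occs = [
            _Occ(bid, block_class[bid], block_length[bid], "+")
            for bid in range(1, n_anc + 1)
            if g in presence[bid]
        ]
        for _ in range(config.n_unique_per_genome):
            length = int(rng.integers(lo, hi + 1))
            block_class[next_id] = "U"
            block_length[next_id] = length
            presence[next_id] = {g}
            pos = int(rng.integers(0, len(occs) + 1))
            occs.insert(pos, _Occ(next_id, "U", length, "+"))
            next_id += 1
        occ_lists.append(occs)

    _apply_events(occ_lists, core_ids, config, rng)

    # assign coordinates per genome/sequence with small random gaps
    gap_lo, gap_hi = config.gap_range
    intervals: dict[int, list[BlockInterval]] = {bid: [] for bid in block_class}
    catalog: list[GenomeMeta] = []
    genome_orders: dict[str, tuple[tuple[int, str, str], ...]] = {}
    for g, occs in enumerate(occ_lists):
        gid = f"g{g}"
        seq_names = sorted({o.seq for o in occs}) or ["chr1"]
        seq_names.sort(key=lambda s: (s != "chr1", s))  # chr1 first
        cursors = {s: 0 for s in seq_names}
        order: list[tuple[int, str, str]] = []
        for o in occs:
            gap = int(rng.integers(gap_lo, gap_hi + 1))
            start = cursors[o.seq] + gap
            end = start + o.length
            cursors[o.seq] = end
            intervals[o.block_id].append(BlockInterval(gid, o.seq, start, end, o.strand))
            order.append((o.block_id, o.strand, o.seq))
        seq_lengths = {s: cursors[s] + int(rng.integers(gap_lo, gap_hi + 1)) + 1 for s in seq_names}
        catalog.append(
            GenomeMeta(
                genome_id=gid,
                display_name=f"synthetic genome {g}",
                seq_names=tuple(seq_names),
                seq_lengths=seq_lengths,
            )
        )
        genome_orders[gid] = tuple(order)

    blocks = [
        AlignmentBlock(block_id=bid, intervals=ivs)
        for bid, ivs in sorted(intervals.items())
        if ivs
    ]
    truth = TruthTable(
        block_class=block_class,
        block_length=block_length,
        planted_consensus=tuple(core_ids),
        genome_orders=genome_orders,
        events={
            "inversions": config.inversions,
            "translocations": config.translocations,
            "variable_regions": config.variable_regions,
        },
    )
    return SyntheticPanGenome(
        config=config, catalog=catalog, alignment_blocks=blocks, truth=truth
    )


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Named desk-scale scenarios covering the qualitative regimes seen in
    real pan-genomes: fully collinear assemblies, a single large inversion,
    a translocation-rich set, and a shuffled highly-variable region."""
    return {
        "collinear": ScenarioConfig(
            n_genomes=4, n_core=40, n_dispensable=12, n_unique_per_genome=4, seed=seed
        ),
        "inversion": ScenarioConfig(
            n_genomes=4,
            n_core=40,
            n_dispensable=12,
            n_unique_per_genome=4,
            inversions=(Inversion(genome=1, start_rank=12, length=6),),
            seed=seed + 1,
        ),
        "translocation": ScenarioConfig(
            n_genomes=4,
            n_core=40,
            n_dispensable=12,
            n_unique_per_genome=4,
            translocations=(
                Translocation(genome=0, source_rank=5, dest_rank=30),
                Translocation(genome=2, source_rank=18, dest_rank=36),
                Translocation(genome=3, source_rank=25, dest_rank=2),
            ),
            seed=seed + 2,
        ),
        "variable-region": ScenarioConfig(
            n_genomes=5,
            n_core=40,
            n_dispensable=10,
            n_unique_per_genome=3,
            variable_regions=(VariableRegion(start_rank=15, length=8),),
            seed=seed + 3,
        ),
    }


def divergent_pair(
    seed: int = 0,
    base: ScenarioConfig | None = None,
    miss_core_frac: float = 0.35,
    split_core_frac: float = 0.3,
    extra_unique: int = 12,
) -> tuple[SyntheticPanGenome, SyntheticPanGenome]:
    """A scenario and the same scenario after adding one divergent genome.

    The added genome misses a fraction of the formerly-core blocks (which
    therefore become dispensable), fragments a fraction of the surviving
    core blocks into two (both halves still core), and contributes many
    unique blocks — the signature of aligning a distant accession: more
    blocks overall, strictly less cumulative core content.
    """
    base_cfg = base or ScenarioConfig(
        n_genomes=4, n_core=40, n_dispensable=12, n_unique_per_genome=4, seed=seed
    )
    base_pg = generate(base_cfg)
    rng = np.random.default_rng(seed + 10_007)
    n_core = base_cfg.n_core

    missed = rng.random(n_core) < miss_core_frac
    if not missed.any():
        missed[int(rng.integers(0, n_core))] = True
    split = (~missed) & (rng.random(n_core) < split_core_frac)

    core_ids = list(base_pg.truth.planted_consensus)
    bl = base_pg.truth.block_length

    blocks: dict[int, list[BlockInterval]] = {
        b.block_id: list(b.intervals) for b in base_pg.alignment_blocks
    }
    next_id = max(blocks) + 1

    # fragment selected core blocks in every existing genome
    split_map: dict[int, int] = {}
    for r, bid in enumerate(core_ids):
        if not split[r]:
            continue
        half = max(1, bl[bid] // 2)
        if bl[bid] - half < 1:
            continue
        new_id = next_id
        next_id += 1
        split_map[bid] = new_id
        new_ivs_a: list[BlockInterval] = []
        new_ivs_b: list[BlockInterval] = []
        for iv in blocks[bid]:
            if iv.strand == "+":
                cut = iv.start + half
                new_ivs_a.append(replace(iv, end=cut))
                new_ivs_b.append(replace(iv, start=cut))
            else:
                cut = iv.end - half
                new_ivs_a.append(replace(iv, start=cut))
                new_ivs_b.append(replace(iv, end=cut))
        blocks[bid] = new_ivs_a
        blocks[new_id] = new_ivs_b

    # lay out the divergent genome: planted order minus missed cores, halves
    # adjacent, heavy unique load, plus a mild shuffle of a central window
    gid = f"g{base_cfg.n_genomes}"
    div_occ: list[tuple[int, int]] = []  # (block_id, length)
    for r, bid in enumerate(core_ids):
        if missed[r]:
            continue
        if bid in split_map:
            half = max(1, bl[bid] // 2)
            div_occ.append((bid, half))
            div_occ.append((split_map[bid], bl[bid] - half))
        else:
            div_occ.append((bid, bl[bid]))
    for _ in range(extra_unique):
        length = int(rng.integers(*[v for v in base_cfg.block_length_range]) )
        blocks[next_id] = []
        div_occ.insert(int(rng.integers(0, len(div_occ) + 1)), (next_id, length))
        next_id += 1
    if len(div_occ) > 8:
        w0 = len(div_occ) // 3
        w1 = 2 * len(div_occ) // 3
        window = div_occ[w0:w1]
        perm = rng.permutation(len(window))
        div_occ[w0:w1] = [window[k] for k in perm]

    cursor = 0
    for bid, length in div_occ:
        gap = int(rng.integers(*base_cfg.gap_range) + 1)
        start = cursor + gap
        end = start + length
        cursor = end
        blocks.setdefault(bid, []).append(BlockInterval(gid, "chr1", start, end, "+"))

    catalog = list(base_pg.catalog) + [
        GenomeMeta(
            genome_id=gid,
            display_name="divergent accession",
            seq_names=("chr1",),
            seq_lengths={"chr1": cursor + 10},
        )
    ]
    ext_blocks = [
        AlignmentBlock(block_id=bid, intervals=ivs)
        for bid, ivs in sorted(blocks.items())
        if ivs
    ]
    n_ext = base_cfg.n_genomes + 1
    ext_class = {
        b.block_id: (
            "C" if len(b.intervals) == n_ext else "U" if len(b.intervals) == 1 else "D"
        )
        for b in ext_blocks
    }
    ext_truth = TruthTable(
        block_class=ext_class,
        block_length={b.block_id: b.intervals[0].length for b in ext_blocks},
        planted_consensus=base_pg.truth.planted_consensus,
        genome_orders={},
        events={"divergent_genome": gid},
    )
    ext = SyntheticPanGenome(
        config=replace(base_cfg, n_genomes=n_ext),
        catalog=catalog,
        alignment_blocks=ext_blocks,
        truth=ext_truth,
    )
    return base_pg, ext
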