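"""BED tracks and dot-plot data for pan-genome visualization.

Every genome (plus the consensus) becomes a browser track of colored
blocks:

* light blue — core blocks collinear with the consensus (same relative
  order and orientation),
* dark blue  — core blocks translocated relative to the consensus,
* pink       — core blocks inverted relative to the consensus,
* green      — dispensable blocks,
* red        — unique blocks.

Collinearity is decided per genome by decomposing its core-block order into
maximal runs (consecutive consensus ranks, forward runs with matching
orientation, reversed runs with flipped orientation) and chaining runs with
a maximum-weight increasing chain over their rank intervals: runs on the
chain are in place (forward -> collinear, reversed -> inverted), runs off
the chain are translocated.  This reproduces the visual semantics of a
synteny plot: a planted inversion of k blocks yields exactly k inverted
blocks, a relocated block an isolated translocation.

Two BED variants are emitted: *plain* (real genome coordinates) and
*gap-aligned*, where all tracks share a virtual axis on which every core
block occupies the same horizontal interval and inter-core stretches are
padded to the widest genome's content so columns line up vertically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Mapping, Sequence

from .blocks import BlockClass, BlockOccurrence, GenomeBlockSequence
from .refine import ConsensusOrdering

__all__ = [
    "TrackRecord",
    "DotPlotPoint",
    "COLORS",
    "classify_core_rendering",
    "make_track_records",
    "write_bed",
    "dotplot_points",
    "write_dotplot_tsv",
    "render_dotplot",
    "gff3_track",
]

COLORS = {
    "core_collinear": "173,216,230",   # light blue
    "core_translocated": "0,0,139",    # dark blue
    "core_inverted": "255,105,180",    # pink
    "dispensable": "0,128,0",          # green
    "unique": "255,0,0",               # red
    "annotation": "128,128,128",       # grey (GFF3 pass-through)
}


@dataclass(frozen=True)
class TrackRecord:
    track_id: str
    seq_name: str
    start: int
    end: int
    name: str
    color_class: str
    strand: str

    def bed_line(self) -> str:
        return "\t".join(
            [
                self.seq_name,
                str(self.start),
                str(self.end),
                self.name,
                "0",
                self.strand,
                COLORS.get(self.color_class, "0,0,0"),
            ]
        )


@dataclass(frozen=True)
class DotPlotPoint:
    genome_id: str
    block_id: int
    consensus_x: float
    genome_y: float
    genome_y_raw: float
    orientation_mark: str  # collinear | inverted | translocated


def _runs(ranked: list[tuple[int, int, int]]) -> list[dict]:
    """Split [(rank, rel_orientation, occ_index), ...] into maximal runs.

    A forward run steps rank +1 with rel=+1 throughout; a reversed run steps
    rank -1 with rel=-1 throughout.  Singletons take their own rel sign.
    """
    runs: list[dict] = []
    for rank, rel, idx in ranked:
        if runs:
            r = runs[-1]
            last = r["ranks"][-1]
            if rel == r["rel"] and rank == last + rel:
                r["ranks"].append(rank)
                r["idx"].append(idx)
                continue
        runs.append({"ranks": [rank], "idx": [idx], "rel": rel})
    for r in runs:
        r["dir"] = r["rel"]
        r["lo"] = min(r["ranks"])
        r["hi"] = max(r["ranks"])
    return runs


def _chain_runs(runs: list[dict]) -> set[int]:
    """Maximum-weight chain of runs with strictly increasing rank intervals.

    Weight is run length; ties prefer the earlier predecessor, keeping the
    result deterministic.  Returns indices of chained runs.
    """
    k = len(runs)
    best = [0] * k
    prev = [-1] * k
    for i in range(k):
        w = len(runs[i]["ranks"])
        best[i] = w
        for j in range(i):
            if runs[j]["hi"] < runs[i]["lo"] and best[j] + w > best[i]:
                best[i] = best[j] + w
                prev[i] = j
    if k == 0:
        return set()
    end = max(range(k), key=lambda i: (best[i], -i))
    chain: set[int] = set()
    while end != -1:
        chain.add(end)
        end = prev[end]
    return chain


def classify_core_rendering(
    consensus: ConsensusOrdering, seqs: Sequence[GenomeBlockSequence]
) -> dict[tuple[str, int], str]:
    """Color class of every (genome, core block) pair relative to the consensus."""
    out: dict[tuple[str, int], str] = {}
    for gs in seqs:
        ranked: list[tuple[int, int, int]] = []
        occs = gs.core_occurrences()
        for idx, occ in enumerate(occs):
            rank = consensus.rank.get(occ.block_id)
            if rank is None:
                continue
            strand = 1 if occ.strand == "+" else -1
            rel = strand * consensus.orientation[occ.block_id]
            ranked.append((rank, rel, idx))
        runs = _runs(ranked)
        chain = _chain_runs(runs)
        for ri, run in enumerate(runs):
            if ri in chain:
                cls = "core_collinear" if run["dir"] > 0 else "core_inverted"
            else:
                cls = "core_translocated"
            for idx in run["idx"]:
                out[(gs.genome_id, occs[idx].block_id)] = cls
    return out


def _class_of(occ: BlockOccurrence, rendering: Mapping[tuple[str, int], str], gid: str) -> str:
    if occ.block_class is BlockClass.DISPENSABLE:
        return "dispensable"
    if occ.block_class is BlockClass.UNIQUE:
        return "unique"
    return rendering.get((gid, occ.block_id), "core_translocated")


def make_track_records(
    consensus: ConsensusOrdering,
    seqs: Sequence[GenomeBlockSequence],
    labels: Mapping[int, str],
    rendering: Mapping[tuple[str, int], str] | None = None,
) -> dict[str, list[TrackRecord]]:
    """Plain-mode track records: one track per genome plus the consensus."""
    if rendering is None:
        rendering = classify_core_rendering(consensus, seqs)
    tracks: dict[str, list[TrackRecord]] = {}
    consensus_track = [
        TrackRecord(
            track_id="consensus",
            seq_name=cb.group,
            start=cb.start,
            end=cb.end,
            name=labels.get(cb.block_id, f"C?{cb.block_id}"),
            color_class="core_collinear",
            strand="+" if cb.orientation >= 0 else "-",
        )
        for cb in consensus.blocks
    ]
    tracks["consensus"] = consensus_track
    for gs in seqs:
        tracks[gs.genome_id] = [
            TrackRecord(
                track_id=gs.genome_id,
                seq_name=occ.seq_name,
                start=occ.start,
                end=occ.end,
                name=occ.class_label,
                color_class=_class_of(occ, rendering, gs.genome_id),
                strand=occ.strand,
            )
            for occ in gs.occurrences
        ]
    return tracks


def _gap_aligned_layout(
    consensus: ConsensusOrdering, seqs: Sequence[GenomeBlockSequence]
) -> tuple[dict[int, tuple[int, int]], dict[str, dict[int, list[BlockOccurrence]]], dict[int, int], int]:
    """Virtual-axis layout shared by all gap-aligned tracks.

    Returns (core block -> virtual interval, per-genome slot contents,
    slot -> width, total width).  Slot i holds each genome's non-core
    content that follows the i-th consensus core block in that genome's own
    order (slot -1 precedes the first).  Slot width is the maximum summed
    content length over genomes, so every genome fits.
    """
    order = [cb.block_id for cb in consensus.blocks]
    slot_contents: dict[str, dict[int, list[BlockOccurrence]]] = {}
    slot_width: dict[int, int] = {i: 0 for i in range(-1, len(order))}
    for gs in seqs:
        slots: dict[int, list[BlockOccurrence]] = {}
        current = -1
        for occ in gs.occurrences:
            if occ.block_class is BlockClass.CORE and occ.block_id in consensus.rank:
                current = consensus.rank[occ.block_id]
            else:
                slots.setdefault(current, []).append(occ)
        slot_contents[gs.genome_id] = slots
        for slot, occs in slots.items():
            width = sum(o.end - o.start for o in occs)
            if width > slot_width.setdefault(slot, 0):
                slot_width[slot] = width
    core_iv: dict[int, tuple[int, int]] = {}
    cursor = slot_width.get(-1, 0)
    for i, bid in enumerate(order):
        start, end = consensus.interval[bid]
        length = end - start
        core_iv[bid] = (cursor, cursor + length)
        cursor += length + slot_width.get(i, 0)
    return core_iv, slot_contents, slot_width, cursor


def make_gap_aligned_records(
    consensus: ConsensusOrdering,
    seqs: Sequence[GenomeBlockSequence],
    labels: Mapping[int, str],
    rendering: Mapping[tuple[str, int], str] | None = None,
    axis_name: str = "pan",
) -> dict[str, list[TrackRecord]]:
    """Gap-aligned tracks: every core block occupies the same interval in
    every track; non-core content packs left-to-right in padded gaps."""
    if rendering is None:
        rendering = classify_core_rendering(consensus, seqs)
    if len({p for p in (cb.path_index for cb in consensus.blocks)}) > 1:
        warnings.warn(
            "gap-aligned tracks requested on a multi-path consensus; "
            "paths are concatenated in consensus order"
        )
    core_iv, slot_contents, _, _ = _gap_aligned_layout(consensus, seqs)
    tracks: dict[str, list[TrackRecord]] = {}
    tracks["consensus"] = [
        TrackRecord(
            track_id="consensus",
            seq_name=axis_name,
            start=core_iv[cb.block_id][0],
            end=core_iv[cb.block_id][1],
            name=labels.get(cb.block_id, f"C?{cb.block_id}"),
            color_class="core_collinear",
            strand="+" if cb.orientation >= 0 else "-",
        )
        for cb in consensus.blocks
    ]
    order = [cb.block_id for cb in consensus.blocks]
    slot_start: dict[int, int] = {}
    slot_start[-1] = 0
    for i, bid in enumerate(order):
        slot_start[i] = core_iv[bid][1]
    for gs in seqs:
        recs: list[TrackRecord] = []
        for occ in gs.occurrences:
            if occ.block_class is BlockClass.CORE and occ.block_id in core_iv:
                s, e = core_iv[occ.block_id]
                recs.append(
                    TrackRecord(
                        track_id=gs.genome_id,
                        seq_name=axis_name,
                        start=s,
                        end=e,
                        name=occ.class_label,
                        color_class=_class_of(occ, rendering, gs.genome_id),
                        strand=occ.strand,
                    )
                )
        for slot, occs in slot_contents[gs.genome_id].items():
            cursor = slot_start.get(slot, 0)
            for occ in occs:
                length = occ.end - occ.start
                recs.append(
                    TrackRecord(
                        track_id=gs.genome_id,
                        seq_name=axis_name,
                        start=cursor,
                        end=cursor + length,
                        name=occ.class_label,
                        color_class=_class_of(occ, rendering, gs.genome_id),
                        strand=occ.strand,
                    )
                )
                cursor += length
        recs.sort(key=lambda r: (r.start, r.end))
        tracks[gs.genome_id] = recs
    return tracks


def write_bed(tracks: Mapping[str, Sequence[TrackRecord]], outdir: str | FsPath) -> list[FsPath]:
    """Write one BED6+1 file per track (column 7 = itemRgb string)."""
    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[FsPath] = []
    for track_id in sorted(tracks):
        path = outdir / f"{track_id}.bed"
        with open(path, "w") as fh:
            for rec in tracks[track_id]:
                fh.write(rec.bed_line() + "\n")
        written.append(path)
    return written


def dotplot_points(
    consensus: ConsensusOrdering,
    seqs: Sequence[GenomeBlockSequence],
    rendering: Mapping[tuple[str, int], str] | None = None,
    stagger_frac: float = 0.01,
) -> list[DotPlotPoint]:
    """One point per (genome, core block): consensus midpoint vs genome
    midpoint, y staggered by genome index to keep overlapping diagonals
    distinguishable."""
    if rendering is None:
        rendering = classify_core_rendering(consensus, seqs)
    span = max((consensus.total_span, 1))
    stagger = stagger_frac * span
    points: list[DotPlotPoint] = []
    for gi, gs in enumerate(seqs):
        for occ in gs.core_occurrences():
            iv = consensus.interval.get(occ.block_id)
            if iv is None:
                continue
            x = (iv[0] + iv[1]) / 2
            y_raw = (occ.start + occ.end) / 2
            mark = rendering.get((gs.genome_id, occ.block_id), "translocated")
            mark = {
                "core_collinear": "collinear",
                "core_inverted": "inverted",
                "core_translocated": "translocated",
            }.get(mark, mark)
            points.append(
                DotPlotPoint(
                    genome_id=gs.genome_id,
                    block_id=occ.block_id,
                    consensus_x=x,
                    genome_y=y_raw + gi * stagger,
                    genome_y_raw=y_raw,
                    orientation_mark=mark,
                )
            )
    return points


def write_dotplot_tsv(points: Sequence[DotPlotPoint], path: str | FsPath) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tblock_id\tconsensus_x\tgenome_y\tgenome_y_raw\tmark\n")
        for p in points:
            fh.write(
                f"{p.genome_id}\t{p.block_id}\t{p.consensus_x:.1f}\t"
                f"{p.genome_y:.1f}\t{p.genome_y_raw:.1f}\t{p.orientation_mark}\n"
            )


def render_dotplot(points: Sequence[DotPlotPoint], path: str | FsPath) -> None:
    """Scatter of all genomes against the consensus axis (PNG/SVG/PDF by
    file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mark_color = {"collinear": "#4878CF", "inverted": "#EE854A", "translocated": "#6ACC64"}
    fig, ax = plt.subplots(figsize=(7, 5))
    genomes = sorted({p.genome_id for p in points})
    markers = ["o", "s", "^", "v", "D", "P", "X", "*"]
    for gi, gid in enumerate(genomes):
        sub = [p for p in points if p.genome_id == gid]
        ax.scatter(
            [p.consensus_x for p in sub],
            [p.genome_y for p in sub],
            c=[mark_color.get(p.orientation_mark, "grey") for p in sub],
            s=12,
            marker=markers[gi % len(markers)],
            label=gid,
            linewidths=0,
        )
    ax.set_xlabel("consensus ordering (bp)")
    ax.set_ylabel("genome coordinate (bp, staggered)")
    ax.legend(fontsize=7, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gff3_track(path: str | FsPath, genome_id: str, feature_types: set[str] | None = None) -> list[TrackRecord]:
    """Validate a GFF3 file and lift its features to a grey plain-mode track.

    Plain-mode track coordinates are genome coordinates, so the lift is the
    identity; only validation and recoloring happen here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records: list[TrackRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feature_types and feat.featuretype not in feature_types:
            continue
        records.append(
            TrackRecord(
                track_id=f"{genome_id}.annotation",
                seq_name=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                name=feat.id or feat.featuretype,
                color_class="annotation",
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return records
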