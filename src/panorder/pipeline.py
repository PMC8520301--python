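"""End-to-end driver: blocks in, consensus + tracks out.

Binds the stages together — read, classify, per-genome ordering, core
permutations per chromosome group, greedy consensus, orientation /
mis-join refinement, coordinate assignment, and track/dot-plot emission —
and writes a reproducible artifact directory.  Every run is deterministic
for a given input; the run log records each resolved knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Sequence

import yaml

from . import blocks as blk
from . import consensus as cns
from . import refine as rfn
from . import tracks as trk
from .alignment_io import AlignmentBlock, GenomeMeta, load_catalog, read_backbone, read_xmfa
from .errors import ConfigError

__all__ = ["PipelineResult", "run_pipeline", "run_files"]


@dataclass
class PipelineResult:
    classified: list[blk.ClassifiedBlock]
    seqs: list[blk.GenomeBlockSequence]
    perms_by_group: dict[str, list[blk.CorePermutation]]
    pathsets: dict[str, cns.PathSet]
    consensus: rfn.ConsensusOrdering
    rendering: dict[tuple[str, int], str]
    core_fraction: float
    core_fraction_per_genome: dict[str, float]
    params: dict = field(default_factory=dict)

    @property
    def n_paths(self) -> int:
        return len(self.consensus.paths)


def run_pipeline(
    alignment_blocks: Sequence[AlignmentBlock],
    catalog: Sequence[GenomeMeta],
    threshold_frac: float = 0.8,
    signed_edit: bool = False,
) -> PipelineResult:
    """Run classification, consensus construction and refinement in memory."""
    if not (0 < threshold_frac <= 1):
        raise ConfigError(f"threshold must be in (0, 1], got {threshold_frac}")
    n = len(catalog)
    classified = blk.classify_blocks(alignment_blocks, n)
    seqs = blk.genome_sequences(classified, catalog)
    groups = blk.core_groups(classified)
    perms_by_group = blk.grouped_core_permutations(seqs, groups)

    pathsets: dict[str, cns.PathSet] = {}
    final_by_group: dict[str, list[cns.Path]] = {}
    for group, perms in perms_by_group.items():
        table = cns.build_neighbor_table(perms)
        ps = cns.build_pathset(perms, table)
        pathsets[group] = ps
        finals: list[cns.Path] = []
        for path in ps.paths:
            finals.extend(rfn.split_misjoins(path, perms, threshold_frac))
        final_by_group[group] = finals

    consensus = rfn.assign_coordinates(final_by_group, perms_by_group, classified)
    rendering = trk.classify_core_rendering(consensus, seqs)
    frac, per_genome = blk.core_fraction(classified, catalog)
    return PipelineResult(
        classified=classified,
        seqs=seqs,
        perms_by_group=perms_by_group,
        pathsets=pathsets,
        consensus=consensus,
        rendering=rendering,
        core_fraction=frac,
        core_fraction_per_genome=per_genome,
        params={"threshold_frac": threshold_frac, "signed_edit": signed_edit,
                "seed_rule": "lowest unplaced block id",
                "tie_break": "lower block id / forward orientation"},
    )


def _write_consensus_tsv(result: PipelineResult, path: FsPath) -> None:
    labels = {cb.block_id: cb.class_label for cb in result.classified}
    with open(path, "w") as fh:
        fh.write("rank\tblock\tgroup\tconsensus_start\tconsensus_end\torientation\tpath\n")
        for i, cb in enumerate(result.consensus.blocks):
            fh.write(
                f"{i}\t{labels[cb.block_id]}\t{cb.group}\t{cb.start}\t{cb.end}\t"
                f"{'+' if cb.orientation >= 0 else '-'}\t{cb.path_index}\n"
            )


def run_files(
    input_path: str | FsPath,
    catalog_path: str | FsPath,
    outdir: str | FsPath,
    input_format: str = "xmfa",
    threshold_frac: float = 0.8,
    signed_edit: bool = False,
    gap_aligned: bool = False,
    gff3: str | FsPath | None = None,
    gff3_genome: str | None = None,
    make_plot: bool = True,
) -> PipelineResult:
    """File-level entry point: parse inputs, run, write the artifact set."""
    catalog = load_catalog(catalog_path)
    if input_format == "xmfa":
        alignment_blocks = read_xmfa(input_path, catalog)
    elif input_format == "backbone":
        alignment_blocks = read_backbone(input_path, catalog)
    else:
        raise ConfigError(f"unknown input format {input_format!r}")
    result = run_pipeline(alignment_blocks, catalog, threshold_frac, signed_edit)

    outdir = FsPath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = {cb.block_id: cb.class_label for cb in result.classified}

    summary = blk.summary_table(result.classified, catalog)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "core_fraction.tsv", "w") as fh:
        fh.write("genome\tcore_fraction\n")
        fh.write(f"ALL\t{result.core_fraction:.6f}\n")
        for gid, f in sorted(result.core_fraction_per_genome.items()):
            fh.write(f"{gid}\t{f:.6f}\n")
    _write_consensus_tsv(result, outdir / "consensus.tsv")

    plain = trk.make_track_records(result.consensus, result.seqs, labels, result.rendering)
    if gff3 is not None:
        gid = gff3_genome or catalog[0].genome_id
        extra = trk.gff3_track(gff3, gid)
        if extra:
            plain[extra[0].track_id] = extra
    trk.write_bed(plain, outdir / "bed" / "plain")
    if gap_aligned:
        gapped = trk.make_gap_aligned_records(
            result.consensus, result.seqs, labels, result.rendering
        )
        trk.write_bed(gapped, outdir / "bed" / "gap_aligned")

    points = trk.dotplot_points(result.consensus, result.seqs, result.rendering)
    trk.write_dotplot_tsv(points, outdir / "dotplot.tsv")
    if make_plot:
        trk.render_dotplot(points, outdir / "dotplot.png")

    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "input": str(input_path),
                "format": input_format,
                "catalog": str(catalog_path),
                "n_genomes": len(catalog),
                "n_blocks": len(alignment_blocks),
                "n_core": sum(
                    1 for c in result.classified if c.block_class is blk.BlockClass.CORE
                ),
                "n_paths": result.n_paths,
                "core_fraction": float(result.core_fraction),
                "parameters": result.params,
            },
            fh,
            sort_keys=False,
        )
    return result
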