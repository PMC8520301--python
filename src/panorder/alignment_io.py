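"""Read and write multiple-genome-alignment block coordinates.

Two on-disk dialects are supported, both produced by whole-genome multiple
aligners of the Mauve family:

* **XMFA** (eXtended Multi-FastA): groups of FASTA records separated by ``=``
  lines, headers of the form ``> seqIndex:start-end strand [file]``.  The
  sequence payload (gapped residues) is parsed for well-formedness but not
  stored — downstream analysis needs only coordinates, strands and block
  membership.
* **backbone**: a tab-separated table with one row per block and one signed
  1-based coordinate pair per genome; ``0 0`` marks a genome absent from the
  block, a negative pair marks the reverse strand.

File coordinates are 1-based inclusive; everything in memory is 0-based
half-open (the convention of the BED sinks this package feeds).  A *genome
catalog* resolves XMFA sequence indices to ``(genome, sequence)`` pairs and
carries sequence lengths for bounds checking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import CatalogError, CoordinateError, InvariantError, ParseError

__all__ = [
    "GenomeMeta",
    "BlockInterval",
    "AlignmentBlock",
    "load_catalog",
    "dump_catalog",
    "flat_sequence_index",
    "read_xmfa",
    "write_xmfa",
    "read_backbone",
    "write_backbone",
]


@dataclass(frozen=True)
class GenomeMeta:
    """Identity and dimensions of one input genome.

    ``seq_names`` preserves the order sequences were listed in the catalog;
    that order defines the concatenated coordinate space used by the
    backbone dialect for multi-sequence genomes.
    """

    genome_id: str
    display_name: str
    seq_names: tuple[str, ...]
    seq_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name in self.seq_names:
            length = self.seq_lengths.get(name)
            if length is None or length <= 0:
                raise CatalogError(
                    f"genome {self.genome_id!r}: sequence {name!r} has "
                    f"non-positive or missing length"
                )

    @property
    def total_length(self) -> int:
        return sum(self.seq_lengths[s] for s in self.seq_names)

    def seq_offset(self, seq_name: str) -> int:
        """Cumulative bp offset of ``seq_name`` in the concatenated genome."""
        offset = 0
        for name in self.seq_names:
            if name == seq_name:
                return offset
            offset += self.seq_lengths[name]
        raise CatalogError(f"genome {self.genome_id!r} has no sequence {seq_name!r}")


@dataclass(frozen=True)
class BlockInterval:
    """A signed genomic interval, 0-based half-open."""

    genome_id: str
    seq_name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvariantError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.genome_id}/{self.seq_name}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentBlock:
    """One aligned region: at most one interval per genome."""

    block_id: int
    intervals: list[BlockInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise InvariantError(f"block {self.block_id} has no intervals")
        seen: set[str] = set()
        for iv in self.intervals:
            if iv.genome_id in seen:
                raise InvariantError(
                    f"block {self.block_id}: genome {iv.genome_id!r} appears twice"
                )
            seen.add(iv.genome_id)

    @property
    def genome_ids(self) -> set[str]:
        return {iv.genome_id for iv in self.intervals}

    def interval_for(self, genome_id: str) -> BlockInterval | None:
        for iv in self.intervals:
            if iv.genome_id == genome_id:
                return iv
        return None


# ---------------------------------------------------------------------------
# catalog


def load_catalog(path: str | Path) -> list[GenomeMeta]:
    """Load a genome catalog from YAML.

    Expected shape::

        genomes:
        - genome_id: g0
          display_name: Genome 0        # optional, defaults to genome_id
          sequences:
          - {name: chr1, length: 30500}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "genomes" not in doc:
        raise CatalogError(f"{path}: catalog must contain a 'genomes' list")
    catalog: list[GenomeMeta] = []
    seen: set[str] = set()
    for entry in doc["genomes"]:
        gid = str(entry["genome_id"])
        if gid in seen:
            raise CatalogError(f"{path}: duplicate genome_id {gid!r}")
        seen.add(gid)
        seqs = entry.get("sequences") or []
        names = tuple(str(s["name"]) for s in seqs)
        lengths = {str(s["name"]): int(s["length"]) for s in seqs}
        catalog.append(
            GenomeMeta(
                genome_id=gid,
                display_name=str(entry.get("display_name", gid)),
                seq_names=names,
                seq_lengths=lengths,
            )
        )
    return catalog


def dump_catalog(catalog: Sequence[GenomeMeta], path: str | Path) -> None:
    doc = {
        "genomes": [
            {
                "genome_id": g.genome_id,
                "display_name": g.display_name,
                "sequences": [
                    {"name": s, "length": int(g.seq_lengths[s])} for s in g.seq_names
                ],
            }
            for g in catalog
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def flat_sequence_index(catalog: Sequence[GenomeMeta]) -> list[tuple[str, str]]:
    """XMFA seqIndex ``i`` (1-based) resolves to the i-th (genome, sequence)
    pair in catalog order."""
    return [(g.genome_id, s) for g in catalog for s in g.seq_names]


def _meta_by_id(catalog: Sequence[GenomeMeta]) -> dict[str, GenomeMeta]:
    return {g.genome_id: g for g in catalog}


def _check_bounds(iv: BlockInterval, catalog_map: Mapping[str, GenomeMeta]) -> None:
    meta = catalog_map.get(iv.genome_id)
    if meta is None:
        raise CatalogError(f"unknown genome {iv.genome_id!r}")
    if iv.seq_name not in meta.seq_lengths:
        raise CatalogError(
            f"genome {iv.genome_id!r} has no sequence {iv.seq_name!r}"
        )
    if iv.end > meta.seq_lengths[iv.seq_name]:
        raise CoordinateError(
            f"interval [{iv.start}, {iv.end}) exceeds length "
            f"{meta.seq_lengths[iv.seq_name]} of {iv.genome_id}/{iv.seq_name}"
        )


# ---------------------------------------------------------------------------
# XMFA

_XMFA_HEADER = re.compile(
    r"^>\s*(?P<idx>\d+):(?P<start>\d+)-(?P<end>\d+)\s+(?P<strand>[+-])(?:\s+(?P<file>\S+))?\s*$"
)


def read_xmfa(path: str | Path, genome_catalog: Sequence[GenomeMeta]) -> list[AlignmentBlock]:
    """Parse an XMFA file into alignment blocks.

    One block per ``=``-terminated group.  Entries with the ``0-0`` absent
    convention are dropped.  Sequence payload is length-checked against the
    declared interval (gaps excluded) when present, then discarded.
    """
    flat = flat_sequence_index(genome_catalog)
    catalog_map = _meta_by_id(genome_catalog)
    blocks: list[AlignmentBlock] = []
    pending: list[BlockInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                m = _XMFA_HEADER.match(line)
                if m is None:
                    raise ParseError(f"{path}:{lineno}: malformed XMFA header: {line!r}")
                idx = int(m.group("idx"))
                start1, end1 = int(m.group("start")), int(m.group("end"))
                if start1 == 0 and end1 == 0:
                    continue  # absent-genome placeholder entry
                if not (1 <= idx <= len(flat)):
                    raise CatalogError(
                        f"{path}:{lineno}: seqIndex {idx} outside catalog "
                        f"(1..{len(flat)})"
                    )
                gid, seq_name = flat[idx - 1]
                start, end = start1 - 1, end1
                if end <= start:
                    raise CoordinateError(
                        f"{path}:{lineno}: end < start after conversion "
                        f"({start1}-{end1})"
                    )
                iv = BlockInterval(gid, seq_name, start, end, m.group("strand"))
                _check_bounds(iv, catalog_map)
                pending.append(iv)
            elif line.startswith("="):
                if pending:
                    blocks.append(AlignmentBlock(block_id=len(blocks) + 1, intervals=pending))
                    pending = []
            # residue lines are ignored: coordinates fully determine the model
    if pending:
        blocks.append(AlignmentBlock(block_id=len(blocks) + 1, intervals=pending))
    return blocks


def write_xmfa(
    blocks: Iterable[AlignmentBlock],
    genome_catalog: Sequence[GenomeMeta],
    path: str | Path,
    line_width: int = 80,
) -> None:
    """Write blocks as XMFA with placeholder residues of correct length."""
    flat = flat_sequence_index(genome_catalog)
    rev = {pair: i + 1 for i, pair in enumerate(flat)}
    catalog_map = _meta_by_id(genome_catalog)
    with open(path, "w") as fh:
        fh.write("#FormatVersion Mauve1\n")
        for g in genome_catalog:
            fh.write(f"#Sequence {g.genome_id} {g.display_name}\n")
        for block in blocks:
            for iv in block.intervals:
                _check_bounds(iv, catalog_map)
                idx = rev.get((iv.genome_id, iv.seq_name))
                if idx is None:
                    raise CatalogError(
                        f"({iv.genome_id}, {iv.seq_name}) not in catalog"
                    )
                fh.write(f"> {idx}:{iv.start + 1}-{iv.end} {iv.strand} {iv.genome_id}.fa\n")
                seq = "A" * iv.length
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
            fh.write("=\n")


# ---------------------------------------------------------------------------
# Mauve backbone


def _concat_to_local(
    meta: GenomeMeta, start: int, end: int
) -> tuple[str, int, int]:
    """Map a 0-based half-open interval in concatenated space to one sequence."""
    offset = 0
    for name in meta.seq_names:
        length = meta.seq_lengths[name]
        if end <= offset + length:
            if start < offset:
                raise CoordinateError(
                    f"interval [{start}, {end}) spans a sequence boundary in "
                    f"genome {meta.genome_id!r}"
                )
            return name, start - offset, end - offset
        offset += length
    raise CoordinateError(
        f"interval [{start}, {end}) exceeds total length of genome "
        f"{meta.genome_id!r}"
    )


def read_backbone(path: str | Path, genome_catalog: Sequence[GenomeMeta]) -> list[AlignmentBlock]:
    """Parse a Mauve-style backbone coordinate table.

    Header row names columns ``seq0_leftend seq0_rightend seq1_leftend ...``;
    one column pair per catalog genome, coordinates signed 1-based in each
    genome's concatenated sequence space.
    """
    n = len(genome_catalog)
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty backbone file")
        ncols = len(header.split("\t"))
        if ncols % 2 != 0 or ncols != 2 * n:
            raise ParseError(
                f"{path}:1: expected {2 * n} columns (2 per genome), got {ncols}"
            )
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            fields = raw.split("\t")
            if len(fields) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}"
                )
            try:
                values = [int(v) for v in fields]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            intervals: list[BlockInterval] = []
            for gi, meta in enumerate(genome_catalog):
                left, right = values[2 * gi], values[2 * gi + 1]
                if left == 0 and right == 0:
                    continue
                if left > right:
                    raise CoordinateError(
                        f"{path}:{lineno}: left > right for genome "
                        f"{meta.genome_id!r} ({left}, {right})"
                    )
                if (left < 0) != (right < 0):
                    raise ParseError(
                        f"{path}:{lineno}: mixed-sign coordinate pair for genome "
                        f"{meta.genome_id!r} ({left}, {right})"
                    )
                strand = "-" if left < 0 else "+"
                a, b = sorted((abs(left), abs(right)))
                seq_name, start, end = _concat_to_local(meta, a - 1, b)
                iv = BlockInterval(meta.genome_id, seq_name, start, end, strand)
                _check_bounds(iv, _meta_by_id(genome_catalog))
                intervals.append(iv)
            if not intervals:
                raise ParseError(f"{path}:{lineno}: all-zero row (empty block)")
            blocks.append(AlignmentBlock(block_id=len(blocks) + 1, intervals=intervals))
    return blocks


def write_backbone(
    blocks: Iterable[AlignmentBlock],
    genome_catalog: Sequence[GenomeMeta],
    path: str | Path,
) -> None:
    header = "\t".join(
        f"seq{i}_{side}" for i in range(len(genome_catalog)) for side in ("leftend", "rightend")
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for block in blocks:
            cells: list[str] = []
            for meta in genome_catalog:
                iv = block.interval_for(meta.genome_id)
                if iv is None:
                    cells += ["0", "0"]
                    continue
                offset = meta.seq_offset(iv.seq_name)
                left, right = offset + iv.start + 1, offset + iv.end
                if iv.strand == "-":
                    # keep the pair numerically ordered: [-hi, -lo]
                    left, right = -right, -left
                cells += [str(left), str(right)]
            fh.write("\t".join(cells) + "\n")
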