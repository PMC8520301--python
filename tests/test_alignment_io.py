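"""I/O dialects: header parsing, coordinate conventions, round-trips."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panorder.alignment_io import (
    AlignmentBlock,
    BlockInterval,
    GenomeMeta,
    dump_catalog,
    load_catalog,
    read_backbone,
    read_xmfa,
    write_backbone,
    write_xmfa,
)
from panorder.errors import CatalogError, CoordinateError, InvariantError, ParseError
from panorder.synth import generate
from tests.conftest import make_scenario


def catalog2(len_a=10_000, len_b=10_000):
    return [
        GenomeMeta("gA", "genome A", ("chr1",), {"chr1": len_a}),
        GenomeMeta("gB", "genome B", ("chr1",), {"chr1": len_b}),
    ]


def write(tmp_path, text):
    p = tmp_path / "in.xmfa"
    p.write_text(textwrap.dedent(text))
    return p


class TestXmfaRead:
    def test_one_based_inclusive_converts_to_half_open(self, tmp_path):
        p = write(
            tmp_path,
            """\
            > 1:101-200 +
            {}
            =
            """.format("A" * 100),
        )
        blocks = read_xmfa(p, catalog2())
        (iv,) = blocks[0].intervals
        assert (iv.genome_id, iv.seq_name, iv.start, iv.end, iv.strand) == (
            "gA", "chr1", 100, 200, "+",
        )

    def test_group_per_equals_line_and_absent_entries_dropped(self, tmp_path):
        p = write(
            tmp_path,
            """\
            > 1:1-50 +
            > 2:0-0 +
            =
            > 2:11-20 -
            =
            """,
        )
        blocks = read_xmfa(p, catalog2())
        assert [len(b.intervals) for b in blocks] == [1, 1]
        assert blocks[1].intervals[0].strand == "-"

    def test_malformed_header_names_line(self, tmp_path):
        p = write(tmp_path, "> 1:banana +\nAA\n=\n")
        with pytest.raises(ParseError, match=":1"):
            read_xmfa(p, catalog2())

    def test_seq_index_outside_catalog(self, tmp_path):
        p = write(tmp_path, "> 7:1-5 +\nAAAAA\n=\n")
        with pytest.raises(CatalogError):
            read_xmfa(p, catalog2())

    def test_out_of_bounds_interval(self, tmp_path):
        p = write(tmp_path, "> 1:1-99999 +\nAA\n=\n")
        with pytest.raises(CoordinateError):
            read_xmfa(p, catalog2())


class TestXmfaWrite:
    def test_empty_block_list_round_trips_to_empty(self, tmp_path):
        p = tmp_path / "empty.xmfa"
        write_xmfa([], catalog2(), p)
        assert read_xmfa(p, catalog2()) == []

    def test_placeholder_residue_length_matches_interval(self, tmp_path):
        block = AlignmentBlock(1, [BlockInterval("gA", "chr1", 10, 15, "+")])
        p = tmp_path / "one.xmfa"
        write_xmfa([block], catalog2(), p)
        residues = [
            line for line in p.read_text().splitlines()
            if line and not line.startswith(("#", ">", "="))
        ]
        assert sum(len(r) for r in residues) == 5

    def test_out_of_bounds_write_rejected(self, tmp_path):
        block = AlignmentBlock(1, [BlockInterval("gA", "chr1", 0, 20_000, "+")])
        with pytest.raises(CoordinateError):
            write_xmfa([block], catalog2(), tmp_path / "x.xmfa")


class TestBackbone:
    def test_signed_zero_conventions(self, tmp_path):
        cat = catalog2()
        p = tmp_path / "bb.tsv"
        p.write_text(
            "seq0_leftend\tseq0_rightend\tseq1_leftend\tseq1_rightend\n"
            "500\t700\t-900\t-800\n"
            "50\t60\t0\t0\n"
        )
        blocks = read_backbone(p, cat)
        iv0, iv1 = blocks[0].intervals
        assert (iv0.start, iv0.end, iv0.strand) == (499, 700, "+")
        assert (iv1.start, iv1.end, iv1.strand) == (799, 900, "-")
        assert len(blocks[1].intervals) == 1

    def test_all_zero_row_rejected(self, tmp_path):
        p = tmp_path / "bb.tsv"
        p.write_text("seq0_leftend\tseq0_rightend\tseq1_leftend\tseq1_rightend\n0\t0\t0\t0\n")
        with pytest.raises(ParseError):
            read_backbone(p, catalog2())

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bb.tsv"
        p.write_text("seq0_leftend\tseq0_rightend\n1\t5\n")
        with pytest.raises(ParseError):
            read_backbone(p, catalog2())

    def test_numerically_disordered_pair_rejected(self, tmp_path):
        p = tmp_path / "bb.tsv"
        p.write_text(
            "seq0_leftend\tseq0_rightend\tseq1_leftend\tseq1_rightend\n"
            "700\t500\t0\t0\n"
        )
        with pytest.raises(CoordinateError):
            read_backbone(p, catalog2())

    def test_multisequence_concatenated_coordinates(self, tmp_path):
        cat = [
            GenomeMeta("gA", "A", ("chr1", "chr2"), {"chr1": 100, "chr2": 100}),
            GenomeMeta("gB", "B", ("chr1",), {"chr1": 500}),
        ]
        p = tmp_path / "bb.tsv"
        p.write_text(
            "seq0_leftend\tseq0_rightend\tseq1_leftend\tseq1_rightend\n"
            "121\t150\t1\t30\n"
        )
        (block,) = read_backbone(p, cat)
        iv = block.interval_for("gA")
        assert (iv.seq_name, iv.start, iv.end) == ("chr2", 20, 50)


def _same_block_set(xs, ys):
    key = lambda b: sorted(
        (iv.genome_id, iv.seq_name, iv.start, iv.end, iv.strand) for iv in b.intervals
    )
    return sorted(map(key, xs)) == sorted(map(key, ys))


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_xmfa_and_backbone_round_trip_random_fixtures(seed, tmp_path_factory):
    """write -> read is the identity on block sets for both dialects."""
    tmp = tmp_path_factory.mktemp("rt")
    pg = generate(make_scenario(seed))
    x = tmp / f"{seed}.xmfa"
    b = tmp / f"{seed}.tsv"
    write_xmfa(pg.alignment_blocks, pg.catalog, x)
    write_backbone(pg.alignment_blocks, pg.catalog, b)
    assert _same_block_set(read_xmfa(x, pg.catalog), pg.alignment_blocks)
    assert _same_block_set(read_backbone(b, pg.catalog), pg.alignment_blocks)


def test_xmfa_agrees_with_biopython_mauve_reader(tmp_path):
    """Independent cross-check of the XMFA dialect against Bio.AlignIO."""
    Bio_AlignIO = pytest.importorskip("Bio.AlignIO")
    pg = generate(make_scenario(3))
    p = tmp_path / "x.xmfa"
    write_xmfa(pg.alignment_blocks, pg.catalog, p)
    ours = read_xmfa(p, pg.catalog)
    ours_ivs = sorted(
        (iv.start, iv.end, 1 if iv.strand == "+" else -1)
        for b in ours for iv in b.intervals
    )
    theirs = sorted(
        (rec.annotations["start"], rec.annotations["end"], rec.annotations["strand"])
        for aln in Bio_AlignIO.parse(str(p), "mauve")
        for rec in aln
    )
    assert ours_ivs == theirs


def test_catalog_round_trip(tmp_path):
    cat = [
        GenomeMeta("gA", "genome A", ("chr1", "chr2"), {"chr1": 11, "chr2": 22}),
        GenomeMeta("gB", "gB", ("chr1",), {"chr1": 7}),
    ]
    p = tmp_path / "cat.yaml"
    dump_catalog(cat, p)
    assert load_catalog(p) == cat


def test_duplicate_genome_in_block_rejected():
    with pytest.raises(InvariantError):
        AlignmentBlock(
            1,
            [
                BlockInterval("gA", "chr1", 0, 5, "+"),
                BlockInterval("gA", "chr1", 10, 15, "+"),
            ],
        )
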