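"""Rendering classification, BED emission, gap alignment, dot-plots."""

import pytest

from panorder.blocks import BlockClass
from panorder.pipeline import run_pipeline
from panorder.synth import Inversion, ScenarioConfig, Translocation, generate
from panorder.tracks import (
    COLORS,
    dotplot_points,
    make_gap_aligned_records,
    make_track_records,
    write_bed,
    write_dotplot_tsv,
)


def _labels(result):
    return {cb.block_id: cb.class_label for cb in result.classified}


class TestRenderingClassification:
    def test_collinear_scenario_all_collinear(self, collinear_result):
        assert set(collinear_result.rendering.values()) == {"core_collinear"}

    def test_planted_inversion_marks_exactly_k_blocks(self, inversion_pg, inversion_result):
        (ev,) = inversion_pg.config.inversions
        marked = [
            (g, b) for (g, b), c in inversion_result.rendering.items()
            if c == "core_inverted"
        ]
        assert len(marked) == ev.length
        assert {g for g, _ in marked} == {f"g{ev.genome}"}
        inverted_ids = {b for _, b in marked}
        planted = set(
            inversion_pg.truth.planted_consensus[ev.start_rank : ev.start_rank + ev.length]
        )
        assert inverted_ids == planted

    def test_planted_translocations_isolated(self, translocation_pg, translocation_result):
        events = translocation_pg.config.translocations
        marked = {
            (g, b) for (g, b), c in translocation_result.rendering.items()
            if c == "core_translocated"
        }
        expected = {
            (f"g{ev.genome}", translocation_pg.truth.planted_consensus[ev.source_rank])
            for ev in events
        }
        assert marked == expected

    def test_cross_chromosome_move_is_translocation(self):
        cfg = ScenarioConfig(
            n_genomes=3, n_core=12, n_dispensable=0, n_unique_per_genome=0,
            translocations=(Translocation(genome=1, source_rank=4, dest_rank=9, dest_seq="chr2"),),
            seed=5,
        )
        pg = generate(cfg)
        res = run_pipeline(pg.alignment_blocks, pg.catalog)
        moved = pg.truth.planted_consensus[4]
        assert res.rendering[("g1", moved)] == "core_translocated"
        others = [c for (g, b), c in res.rendering.items() if (g, b) != ("g1", moved)]
        assert set(others) == {"core_collinear"}


class TestBed:
    def test_track_set_and_color_semantics(self, collinear_pg, collinear_result, tmp_path):
        tracks = make_track_records(
            collinear_result.consensus, collinear_result.seqs, _labels(collinear_result)
        )
        files = write_bed(tracks, tmp_path)
        names = {f.name for f in files}
        assert names == {"consensus.bed"} | {f"{g.genome_id}.bed" for g in collinear_pg.catalog}
        for f in files:
            for line in f.read_text().splitlines():
                chrom, start, end, name, score, strand, rgb = line.split("\t")
                assert int(end) > int(start) and strand in "+-"
                if name.startswith("D"):
                    assert rgb == COLORS["dispensable"]
                elif name.startswith("U"):
                    assert rgb == COLORS["unique"]
                else:
                    assert rgb in (
                        COLORS["core_collinear"],
                        COLORS["core_inverted"],
                        COLORS["core_translocated"],
                    )

    def test_empty_record_set_gives_empty_file(self, tmp_path):
        (f,) = write_bed({"empty": []}, tmp_path)
        assert f.read_text() == ""

    def test_plain_bed_round_trips(self, collinear_result, tmp_path):
        tracks = make_track_records(
            collinear_result.consensus, collinear_result.seqs, _labels(collinear_result)
        )
        write_bed(tracks, tmp_path)
        for tid, recs in tracks.items():
            lines = (tmp_path / f"{tid}.bed").read_text().splitlines()
            parsed = [l.split("\t") for l in lines]
            assert [(p[0], int(p[1]), int(p[2]), p[3], p[5]) for p in parsed] == [
                (r.seq_name, r.start, r.end, r.name, r.strand) for r in recs
            ]

    def test_gap_aligned_core_blocks_vertically_aligned(self, collinear_result, tmp_path):
        gapped = make_gap_aligned_records(
            collinear_result.consensus, collinear_result.seqs, _labels(collinear_result)
        )
        write_bed(gapped, tmp_path)
        core_pos: dict[str, set] = {}
        for f in tmp_path.glob("*.bed"):
            for line in f.read_text().splitlines():
                chrom, start, end, name, *_ = line.split("\t")
                if name.startswith("C"):
                    core_pos.setdefault(name, set()).add((int(start), int(end)))
        assert core_pos and all(len(v) == 1 for v in core_pos.values())

    def test_gap_aligned_tracks_non_overlapping_per_track(self, collinear_result):
        gapped = make_gap_aligned_records(
            collinear_result.consensus, collinear_result.seqs, _labels(collinear_result)
        )
        for recs in gapped.values():
            for a, b in zip(recs, recs[1:]):
                assert b.start >= a.end


class TestDotplot:
    def test_point_count_and_collinear_monotonicity(self, collinear_result):
        pts = dotplot_points(collinear_result.consensus, collinear_result.seqs)
        n = len(collinear_result.seqs)
        m = len(collinear_result.consensus.blocks)
        assert len(pts) == n * m
        for gs in collinear_result.seqs:
            ys = [p.genome_y for p in sorted(
                (q for q in pts if q.genome_id == gs.genome_id),
                key=lambda q: q.consensus_x,
            )]
            assert ys == sorted(ys)

    def test_planted_inversion_antidiagonal_run(self, inversion_pg, inversion_result):
        (ev,) = inversion_pg.config.inversions
        gid = f"g{ev.genome}"
        pts = [
            p for p in dotplot_points(inversion_result.consensus, inversion_result.seqs)
            if p.genome_id == gid and p.orientation_mark == "inverted"
        ]
        assert len(pts) == ev.length
        pts.sort(key=lambda p: p.consensus_x)
        ys = [p.genome_y_raw for p in pts]
        assert ys == sorted(ys, reverse=True)  # anti-diagonal

    def test_tsv_dump_shape(self, collinear_result, tmp_path):
        pts = dotplot_points(collinear_result.consensus, collinear_result.seqs)
        out = tmp_path / "dp.tsv"
        write_dotplot_tsv(pts, out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(pts) + 1
        assert lines[0].split("\t") == [
            "genome_id", "block_id", "consensus_x", "genome_y", "genome_y_raw", "mark",
        ]


def test_gff3_pass_through_lifts_identity(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene1\n"
        "chr1\tsrc\tgene\t501\t700\t.\t-\t.\tID=gene2\n"
    )
    from panorder.tracks import gff3_track

    recs = gff3_track(gff, "g0")
    assert [(r.start, r.end, r.strand) for r in recs] == [(100, 200, "+"), (500, 700, "-")]
    assert all(r.color_class == "annotation" for r in recs)
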