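"""Neighbor statistics, greedy path construction, edit-distance objective."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panorder.blocks import CorePermutation
from panorder.consensus import (
    build_neighbor_table,
    build_pathset,
    edit_distance,
    greedy_extend,
    sum_edit_distance,
    PathSet,
)
from panorder.errors import InvariantError
from panorder.oracle import exact_median
from panorder.synth import ScenarioConfig, VariableRegion, generate
from tests.conftest import make_scenario


def perm(genome, ids):
    return CorePermutation(genome_id=genome, seq_name="chr1", signed_ids=tuple(ids))


class TestNeighborTable:
    def test_unanimous_adjacency_counts(self):
        table = build_neighbor_table([perm(f"g{i}", [1, 2, 3]) for i in range(3)])
        assert dict(table.pooled[2]) == {1: 3, 3: 3}

    def test_mixed_adjacency_counts(self):
        # brute-force tally: 1~2 in g0 and g2; 1~3 in g1 ([1,3,..]) and g2 ([..,1,3])
        table = build_neighbor_table(
            [perm("g0", [1, 2, 3]), perm("g1", [1, 3, 2]), perm("g2", [2, 1, 3])]
        )
        assert dict(table.pooled[1]) == {2: 2, 3: 2}

    def test_adjacency_confined_to_chromosome(self):
        # same block ids on two chromosomes: no cross-sequence adjacency
        p1 = CorePermutation("g0", "chr1", (1, 2))
        p2 = CorePermutation("g0", "chr2", (3, 4))
        table = build_neighbor_table([p1, p2])
        assert 3 not in table.pooled[2] and 2 not in table.pooled[3]


class TestGreedy:
    def test_unanimous_permutation_recovered_from_middle_seed(self):
        perms = [perm(f"g{i}", [1, 2, 3, 4]) for i in range(3)]
        table = build_neighbor_table(perms)
        ps = PathSet()
        path = greedy_extend(2, table, ps)
        assert [abs(x) for x in path.signed_ids] == [1, 2, 3, 4]

    def test_three_way_tie_suspends(self):
        # seed 1 has neighbors 2, 3, 4 each exactly once
        perms = [perm("g0", [2, 1, 5]), perm("g1", [3, 1, 6]), perm("g2", [4, 1, 7])]
        table = build_neighbor_table(perms)
        ps = PathSet()
        path = greedy_extend(1, table, ps)
        assert path.status == "suspended"
        assert path.signed_ids == [1]

    def test_seed_already_assigned_rejected(self):
        perms = [perm("g0", [1, 2])]
        table = build_neighbor_table(perms)
        ps = build_pathset(perms, table)
        with pytest.raises(InvariantError):
            greedy_extend(1, table, ps)

    def test_variable_region_fragments_ordering(self):
        cfg = ScenarioConfig(
            n_genomes=5, n_core=40, n_dispensable=0, n_unique_per_genome=0,
            variable_regions=(VariableRegion(start_rank=15, length=8),), seed=3,
        )
        pg = generate(cfg)
        from panorder.pipeline import run_pipeline

        res = run_pipeline(pg.alignment_blocks, pg.catalog)
        assert res.n_paths >= 2

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_pathset_partitions_core_ids(self, seed):
        pg = generate(make_scenario(seed))
        from panorder import blocks as blk

        classified = blk.classify_blocks(pg.alignment_blocks, pg.config.n_genomes)
        seqs = blk.genome_sequences(classified, pg.catalog)
        perms = blk.grouped_core_permutations(seqs, blk.core_groups(classified))["chr1"]
        ps = build_pathset(perms)
        members = [abs(x) for p in ps.paths for x in p.signed_ids]
        assert sorted(members) == sorted({abs(x) for p in perms for x in p.signed_ids})
        assert len(members) == len(set(members))

    def test_determinism(self):
        pg = generate(make_scenario(11))
        from panorder import blocks as blk

        classified = blk.classify_blocks(pg.alignment_blocks, pg.config.n_genomes)
        seqs = blk.genome_sequences(classified, pg.catalog)
        perms = blk.grouped_core_permutations(seqs, blk.core_groups(classified))["chr1"]
        a = build_pathset(perms)
        b = build_pathset(perms)
        assert [p.signed_ids for p in a.paths] == [p.signed_ids for p in b.paths]


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0),
            ([1, 2, 3], [1, 3, 2], 2),
            ([], [1, 2], 2),
            ([1, 2, 3, 4], [4, 3, 2, 1], 4),  # full reversal, no common subsequence > 1
            ([1, 2, 3], [1, 9, 3], 1),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert edit_distance(a, b) == expected

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.integers(1, 5), max_size=7),
        b=st.lists(st.integers(1, 5), max_size=7),
    )
    def test_metric_properties(self, a, b):
        d = edit_distance(a, b)
        assert d == edit_distance(b, a)
        assert (d == 0) == (a == b)
        assert d <= max(len(a), len(b))

    def test_identical_orderings_give_zero_sum(self):
        perms = [perm(f"g{i}", [3, 1, 2]) for i in range(4)]
        assert sum_edit_distance([3, 1, 2], perms) == 0

    def test_signed_mode_distinguishes_orientation(self):
        perms = [perm("g0", [1, -2, 3])]
        assert sum_edit_distance([1, 2, 3], perms, signed=False) == 0
        assert sum_edit_distance([1, 2, 3], perms, signed=True) == 1


def test_greedy_cost_bounded_below_by_exact_median():
    import numpy as np

    rng = np.random.default_rng(0)
    for _ in range(30):
        m = int(rng.integers(3, 7))
        n = int(rng.integers(2, 5))
        base = list(range(1, m + 1))
        perms = []
        for g in range(n):
            p = base.copy()
            for _ in range(int(rng.integers(0, 3))):
                i, j = rng.integers(0, m, 2)
                p[i], p[j] = p[j], p[i]
            perms.append(perm(f"g{g}", p))
        ps = build_pathset(perms)
        greedy = [abs(x) for p in ps.paths for x in p.signed_ids]
        greedy_cost = sum_edit_distance(greedy, perms)
        _, exact_cost = exact_median(perms)
        assert greedy_cost >= exact_cost


def test_debug_dump_lists_every_path_and_adjacency(tmp_path):
    from panorder.consensus import dump_debug_tsv

    perms = [perm(f"g{i}", [1, 2, 3]) for i in range(3)]
    table = build_neighbor_table(perms)
    ps = build_pathset(perms, table)
    dump_debug_tsv(table, ps, tmp_path)
    paths = (tmp_path / "paths.tsv").read_text().splitlines()
    assert len(paths) == 1 + len(ps.paths)
    neigh = (tmp_path / "neighbors.tsv").read_text().splitlines()
    assert len(neigh) == 1 + sum(len(c) for c in table.pooled.values())
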