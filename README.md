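# panorder

Reference-agnostic pan-genome representation and visualization from
multiple whole-genome alignments.

Declaring one assembly *the* reference biases every downstream comparison.
`panorder` instead takes the block-level output of a multiple whole-genome
aligner (Mauve-family XMFA or backbone coordinate tables) over *n*
same-species assemblies and builds a neutral backbone for the set:

1. **Classification** — every alignment block becomes core (C, present in
   all *n* genomes), dispensable (D, in 2..n−1) or unique (U, in exactly
   one), and each genome is rewritten as an ordered sequence of signed
   block occurrences.
2. **Consensus ordering** — restricted to core blocks, genome *i* is a
   signed permutation σ^i of {1..m}; the consensus σ\* is the ordering
   minimizing Σᵢ L(σ^i, σ\*) with L the Levenshtein distance (the median
   permutation — NP-complete exactly, approximated here by a greedy
   adjacency-frequency path construction).
3. **Refinement** — each greedy path and its reversal are locally aligned
   (match +1, mismatch/gap −1) to every genome; orientation is decided by
   the better summed score, paths scoring below 80% of the attainable
   maximum are split at mis-joins, and path coordinates come from a
   majority vote across genomes.
4. **Visualization data** — per-genome and consensus BED tracks (plain and
   gap-aligned, browser-ready, with the standard color code: light blue
   collinear core, pink inverted, dark blue translocated, green
   dispensable, red unique) and dot-plot data in which inversions appear
   as anti-diagonals and translocations as isolated points.

A synthetic-data module generates pan-genomes with planted truth
(classes, consensus, inversions, translocations, variable regions) in the
same file dialects, so the whole pipeline is testable without any
download.  Brute-force oracles (exact median by enumeration, exhaustive
local alignment) back the test suite at toy scale.

See `docs/methods.md` for the model, the algorithm and its design choices.

## Worked example

Generate a four-genome synthetic pan-genome with one planted six-block
inversion, then run the full pipeline:

```bash
panorder synth --preset inversion --outdir demo/fixture --seed 7
panorder run --input demo/fixture/alignment.xmfa \
             --catalog demo/fixture/catalog.yaml \
             --outdir demo/out --gap-aligned
```

`demo/out/summary.tsv` reports the block partition — 40 core blocks
covering 70.8% of the summed genome length, 12 dispensable, 16 unique:

```
class	count	bp	fraction
core	40	88668	0.7082108626198083
dispensable	12	21621	0.17269169329073483
unique	16	9342	0.07461661341853035
```

`demo/out/run_log.yaml` confirms the consensus collapsed to a single path
of the 40 core blocks:

```
n_genomes: 4
n_blocks: 68
n_core: 40
n_paths: 1
core_fraction: 0.7082108626198083
```

and `demo/out/consensus.tsv` lays the blocks out on the consensus axis:

```
rank	block	group	consensus_start	consensus_end	orientation	path
0	C1	chr1	0	461	+	0
1	C2	chr1	461	702	+	0
```

The BED track of the genome carrying the inversion
(`demo/out/bed/plain/g1.bed`) contains exactly 6 records with the pink
itemRgb `255,105,180` — the six planted inverted blocks — while every
other genome's track has none; `demo/out/dotplot.png` shows them as an
anti-diagonal run against the consensus axis.  Records look like:

```
chr1	870	1331	C1	0	+	173,216,230
chr1	1349	1590	C2	0	+	173,216,230
```

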