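# Methods

## Model

The input is the block-level output of a multiple whole-genome aligner run
over *n* assemblies of one species (XMFA or a Mauve-style backbone
coordinate table).  Each alignment block carries at most one signed
interval per genome.  Blocks are partitioned by occupancy:

* **core (C)** — present in all *n* genomes;
* **dispensable (D)** — present in 2..n−1 genomes;
* **unique (U)** — present in exactly one genome.

Unique blocks are kept distinct from dispensable ones (some of the
literature folds U into D; the summary table has a `merge_unique` flag to
recover that convention).

Restricted to core blocks, genome *i* is a signed permutation σ^i of the
C-block identifiers {1..m}.  The **consensus ordering** σ\* is the
permutation minimizing Σᵢ L(σ^i, σ\*), with L the Levenshtein (edit)
distance over block symbols — the median permutation of the set.  Median
strings under edit distance are NP-complete to compute, so σ\* is
approximated greedily and then repaired by alignment against the genomes.

### Greedy path construction

Adjacencies of core blocks are tallied over all genomes on the C-only
projection (D/U blocks are transparent; counts are per chromosome group;
permutation ends contribute single-sided counts).  Starting from the
lowest-numbered unplaced block, a path grows by the three-way case
analysis on the top-3 neighbor frequencies f1 ≥ f2 ≥ f3 of the current
block (neighbors already placed are excluded before ranking):

* f1 ≥ f2 > f3 — both top neighbors flank the seed (C1 ← seed → C2), then
  the left end is extended as far as possible, then the right end;
* f1 > f2 = f3 — only C1 is added, and the process continues from C1;
* f1 = f2 = f3 (three or more tied candidates) — the neighborhood is
  ambiguous and the path is suspended.

With fewer than three distinct neighbors, missing slots count as
frequency 0; ties between equal frequencies break toward the lower block
id, so the whole construction is deterministic.

**Witness threshold.**  An adjacency is only committed at a path end (or a
seed flank) when at least ⌈n/2⌉ genomes witness it in the path's current
reading frame.  Without this rule a minority-only adjacency — e.g. the one
genome carrying an inversion attests (A,B) at the inversion boundary —
gets appended to a path end and drags the greedy ordering away from the
median; with it, such regions are left to separate paths that the
coordinate vote orders correctly afterwards.  On exhaustive toy grids
(m ≤ 7, all single-inversion placements including boundary-touching ones)
the greedy with this rule matches the brute-force median cost exactly,
which the unguarded case analysis provably does not (committing the
minority adjacency in {[1,2,3], [1,2,3], [−2,−1,3]} costs 4 vs the optimum
2).

Orientation bookkeeping: each genome contributes ordered signed
adjacencies in both reading directions (x→y and −y→−x), and a neighbor
appended at an end takes the sign supported by the majority of those
observations.

### Refinement

Each path (and its reversal: order reversed, signs flipped) is locally
aligned to every genome's core permutation with match +1, mismatch −1,
gap −1 over block symbols; the orientation with the higher summed best
score wins (ties keep forward).  If the summed score falls below
`threshold × Σ_g min(|path|, |σ^g|)` (threshold 0.8 by default), the path
is presumed to contain a mis-join: it is cut at the best-aligned central
span into up to three pieces (left overhang, center, right overhang), each
re-entering orientation and splitting until every piece passes.  Paths of
length ≤ 2 are finalized outright (no mis-join is detectable under ±1
scoring), and a central span covering the whole path finalizes it, so the
recursion terminates.

The attainable maximum is taken as Σ_g min(|path|, |σ^g|) — the best score
the ±1 scheme can reach for those lengths — which makes the threshold
scale-free; it is exposed as a configuration knob.

### Coordinates and orientation of the consensus

Each surviving path is anchored at the **median** over genomes of the bp
start of its best local alignment (a majority vote that is robust to a
minority of rearranged genomes and well-defined for even *n*).  Paths are
sorted by anchor within their chromosome group, groups by name, and
consensus coordinates accumulate from zero with each block spanning its
median per-genome interval length.  Each block's consensus orientation is
set by majority vote of the genome strands (ties keep the path's stored
sign): path-internal signs can be arbitrary where adjacency evidence was
ambiguous (e.g. across a shuffled region), whereas the strand vote is not.

Multi-chromosome inputs are handled by assigning each core block to a
chromosome group (the majority sequence name among its placements) and
computing the consensus per group; a block a minority of genomes placed on
another chromosome surfaces as a translocation at rendering time.

### Rendering classification

The figure semantics — light blue collinear, pink inverted, dark blue
translocated, green dispensable, red unique — require deciding, per
genome, which core blocks are "in place".  Plain longest-increasing-
subsequence chaining on consensus ranks is not enough: the LIS can absorb
one block of an inverted segment, so a planted k-block inversion would
render as 1 inverted + (k−1) translocated.  Instead the genome's core
order is decomposed into maximal runs (rank steps of +1 with matching
orientation = forward run; −1 with flipped orientation = reversed run;
orientation is genome strand × consensus orientation), and a
maximum-weight chain of runs with strictly increasing rank intervals is
selected by dynamic programming (weight = run length, leftmost ties).
Runs on the chain are in place — forward runs render collinear, reversed
runs inverted; runs off the chain render translocated.  A planted k-block
inversion yields exactly k inverted blocks; a relocated block an isolated
translocation; a wholly reverse-complemented chromosome renders inverted.

### Tracks and dot-plots

Plain BED6+1 tracks (one per genome plus the consensus; column 7 is the
itemRgb string) use real genome coordinates.  Gap-aligned tracks place
every core block at a single shared interval on a virtual axis; the
stretch after the i-th consensus block is padded to the widest genome's
non-core content assigned to that stretch (content follows the most recent
core block in each genome's own order), so columns line up vertically in a
browser.  Dot-plots emit one point per (genome, core block): consensus
midpoint vs genome midpoint, with per-genome y-stagger (1% of the
consensus span) so overlapping diagonals stay distinguishable; inversions
appear as anti-diagonal runs, translocations as isolated off-diagonal
points.  GFF3 annotations can be passed through as a grey track in plain
mode (the lift is the identity there); gffutils validates and parses them.

## Synthetic data generator

The generator emulates the aligner's coordinate-level output, not
nucleotide evolution.  An ancestral order interleaves core and dispensable
blocks (uniformly shuffled); dispensable presence patterns are uniform
over subset sizes 2..n−1; per-genome unique blocks are inserted at uniform
positions; block lengths are uniform in 200–1000 bp and inter-block gaps
in 0–50 bp — generic aligner-output scales that exercise every
classification and rearrangement branch at desk scale.  Planted events:
inversions (reverse a core-rank span in one genome, flipping strands,
dragging along interleaved D/U blocks), translocations (move one core
block, optionally to a second chromosome), and variable regions (each
genome shuffles a core-rank span independently).  Default scenario sizes
(4 genomes, 30–40 core blocks) keep exhaustive oracles and repeated runs
fast while leaving room for multi-block events.

A fixed seed reproduces fixtures byte for byte, and the returned truth
table (classes, per-genome orders and strands, planted consensus, events)
is what every downstream check compares against.

What the generator does **not** model — and hence what passing tests do
not show about real data: alignment errors and block-boundary noise,
repeat-induced spurious blocks, nucleotide-level divergence, unequal
assembly contiguity, and aligner-version dependence of block counts.  The
`divergent_pair` construction emulates the *direction* of adding a distant
accession (missed cores become dispensable, surviving cores fragment,
unique load grows) rather than any particular magnitude.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; XMFA/backbone are
  1-based inclusive at the file boundary (backbone reverse-strand pairs
  are numerically ordered, `-900 -800` = [799, 900) on minus).  Block ids
  start at 1: id 0 has no sign in the signed-permutation representation.
* Edit distances compare unsigned symbols by default (the median
  objective is over orderings; orientation is judged by the
  forward/reversed alignment contest); a signed mode is exposed.
* Local-alignment ties resolve to the earliest-ending cell with a
  diagonal-preferring traceback — deterministic, and score-equivalent to
  the leftmost/shortest convention.
* The mis-join threshold applies to the summed score across genomes (a
  per-genome mode would split on any single rearranged genome); 0.8 is
  the default fraction.
* The exact-median oracle enumerates candidate *permutations* of the
  symbol set (not arbitrary strings), matching the consensus-ordering
  formalism; it is feasible to m = 8 and vectorized across candidates.
* Degenerate inputs: a genome absent from every block yields an empty
  (warned) sequence; empty permutations and empty paths score 0
  everywhere; all-zero backbone rows are rejected.

## Known limitations

* The greedy consensus is an approximation; no optimality guarantee
  exists beyond the toy-scale grids checked against the exact oracle.
* Suspended paths in highly variable regions are ordered by coordinate
  vote, not by sequence evidence; their internal order within a shuffled
  region is essentially arbitrary.
* Gap-aligned packing expands every stretch to the widest genome, so
  virtual coordinates grow with the most insertion-rich genome.
* Scaling is bounded in practice by the upstream aligner, not by this
  package; the pipeline itself is near-linear in total block count except
  for the O(path × permutation) alignment step per path and genome.
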