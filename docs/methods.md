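# Methods

## The problem and the approach

Given a set of highly similar nucleotide sequences (intraspecific viral or
organellar genomes are the motivating case), the package computes a multiple
sequence alignment with the center-star heuristic: pick the longest input as
the *center*, align every other sequence pairwise against it, and merge the
pairwise alignments using the center as the shared coordinate system.  The
center-star layout is what makes the merge exact and embarrassingly parallel;
its cost is that sequence-to-sequence relationships other than through the
center are never examined, which is a good trade precisely when all inputs
are close to one another.

Each pairwise alignment runs in three steps:

1. **Anchor discovery.**  An FM-index (suffix array + BWT + rank table) is
   built over the *reversed* center.  Backward search consumes a pattern
   right to left, so feeding it query characters left to right from a fixed
   query position grows the longest center match starting at that position
   one base per step — the per-position maximal-match semantics we want with
   the data structure we have.  Reverse-text hits map back to forward starts
   as `x = |center| − r − w`.  A window qualifies as an anchor when its
   length is strictly greater than the seed threshold `l` and it occurs at
   most `U` times in the center (near-unique, repeat-safe); on multiple
   occurrences the smallest start is kept.  After an anchor of length `w` at
   query position `y` the scan restarts at `y + w − l + 1`, so consecutive
   anchors overlap by at most `l` bases.
2. **Chaining.**  Anchors are nodes of a DAG with an edge `i → j` when `i`
   ends strictly before `j` ends in *both* sequences; the edge weight is
   `w_j` minus the overlap between the two anchors, where the overlap is the
   larger of the center-side and query-side overlaps (never double-counts
   either sequence) clamped at `w_j`.  A weighted longest-increasing-
   subsequence dynamic program over the topological order maximizes the
   first anchor's full length plus edge weights.  Selected anchors are then
   trimmed head-first (the later anchor loses its overlapping prefix, the
   same amount in both coordinates, preserving exactness) so the final chain
   is non-overlapping and strictly increasing in both coordinates.
3. **Segment alignment.**  Anchor blocks are copied verbatim as match
   columns; the flanks and inter-anchor segments are aligned with the
   wavefront algorithm (WFA) under gap-affine costs.  WFA explores scores in
   increasing order, keeping per score and per diagonal the furthest-
   reaching offsets of three states (match/mismatch, gap-in-center,
   gap-in-query) and extending exact-match runs for free; it is exact — no
   adaptive pruning — so every segment alignment is provably optimal for the
   penalty set, and it runs in O(n·s), which is fast exactly when the inputs
   are similar (small optimal score s).  Identical segments and empty sides
   are dispatched without running the wavefronts.

**Merge.**  Each pairwise alignment is summarized by a *gap profile*: how
many gap columns it opens in each of the `|center|+1` slots (before each
center base, plus one trailing slot).  The final profile is the slot-wise
maximum over all pairs; the center row is the center padded by that profile,
and each query row is padded wherever the final profile exceeds its own
profile.  Extra padding is placed at the slot boundary *before* the pair's
own gap columns — any fixed convention preserves the projection property
(restricting the MSA to {center, query k} and deleting mutually gapped
columns reproduces pairwise alignment k byte for byte); fixing one makes the
output deterministic.  The center row is emitted at its original input
position, as common MSA tools do.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `l` (min match length) | 15 | anchors require match length strictly > l; MUMmer-style seed length for near-identical DNA.  Smaller values anchor more at low similarity but admit spurious seeds. |
| `U` (max occurrences) | 10 | windows with more center hits are treated as repeats and skipped. |
| mismatch | 2 | gap-affine cost of a substitution column (match costs 0 by construction). |
| gap open / extend | 3 / 1 | a gap of length k costs 3 + k·1. |
| workers | 1 | process-parallel stage-2 map; output is byte-identical for any worker count because each query's alignment is independent and deterministic. |
| seed | 0 | drives only ambiguous-base resolution in preprocessing (per-record derived seeds, so the result is independent of worker scheduling). |

Preprocessing closes the alphabet to {A,C,G,T}: uppercase, U→T, IUPAC codes
resolved to a seeded random base from the denoted set.  A closed alphabet is
required by both the index and the aligner; determinism is imposed so runs
are reproducible.

## Numerical and tie-breaking choices

- Suffix arrays are built by prefix doubling over `numpy.lexsort`
  (O(n log² n)); any correct construction would do at the scales targeted
  here.  The sentinel `'$'` sorts below every base.
- Rank queries use a full prefix-count table (O(1) lookup, O(σ·n) memory).
- Center selection: longest sequence, lowest input index on ties.
- Anchor occurrence ties: smallest center start.
- Topological order: stable sort by (end_x, end_y, x, y); this is a valid
  topological order because edges require strictly larger ends in both
  coordinates.  Chain DP score ties keep the predecessor earliest in that
  order, which biases toward lexicographically small starts and makes the
  chain unique and reproducible.
- WFA traceback prefers, on equal furthest-reaching offsets, mismatch over
  gap-in-center over gap-in-query, and closing a gap over extending it; all
  co-optimal, one fixed.
- The CIGAR convention is I = gap in the center row, D = gap in the query
  row; it must be fixed for the merge and this is the one used throughout.
- Degenerate inputs: an empty segment pair yields an empty CIGAR; a
  single-sequence input aligns to itself; all-gap columns cannot arise
  (no pairwise column is gapped in both rows, and merging only adds gaps
  against center slots that some pair fills).

## Scoring metrics

SP scores every column and unordered row pair: +1 match, −1 mismatch, −2
when exactly one row is gapped, 0 when both are (a shared gap was already
paid for by each pairwise indel; charging it again would double-count).
Scaled SP = 2·SP / (n(n−1)L) with n rows and width L, so an all-identical
gap-free alignment scores exactly 1.  Q is the fraction of reference-aligned
residue pairs reproduced by the test alignment (denominator: reference pairs
only — the classical developer score); a reference with no aligned pairs
scores 1 by convention.  TC is the fraction of reference columns whose full
residue-index tuple (gap = −1) reappears as a test column, all-gap columns
ignored.  A reproduced column reproduces all its residue pairs, so against a
gap-free reference — where every column carries the same n(n−1)/2 pairs —
TC ≤ Q provably; with gapped references the inequality holds in practice but
is not a theorem (a reference column holding a single residue contributes to
TC's denominator while carrying no pairs at all).
Higher is better for all three; note that a raw SP value is width-dependent,
which is exactly what the scaled form corrects.

## The simulator

The generator emulates the study design the aligner targets: sets of
sequences at controlled pairwise similarity (70–99%) and controlled lengths
(tens to tens of thousands of bases).  It draws a uniform random root and
derives every output sequence independently from it — a star topology, the
same assumption the aligner itself makes, which also makes the true MSA
exact by construction.  Per-site substitution probability p is calibrated
against *pairwise* identity: two leaves agree at a site with probability
(1−p)² + p²/3, so p solves (4/3)p² − 2p + (1−t) = 0 for target t.  Indel
events are layered on top at `indel_fraction` (default 0.1) of the
substitution rate, with geometric lengths (default p = 0.3, mean ≈ 3.3) and
equal insertion/deletion odds; insertions at unrelated leaves sharing a root
slot are left-aligned, the standard convention for unalignable insertions.
A leaf whose residues are entirely deleted (possible only for very short
roots at low similarity) is redrawn.

What the simulator does *not* emulate: phylogenetic tree structure
(correlated divergence), rate heterogeneity along the sequence, codon
structure, and base-composition bias.  Passing tests on this generator
therefore demonstrates correctness of the machinery and good behavior on
star-shaped, homogeneous divergence — not benchmark-grade accuracy on real
clade-structured data.

## Problem sizes used in the test suite

Oracle comparisons run at sizes where the oracles are trustworthy and
exhaustive: Gotoh DP on 1000 pairs up to 200 bases, brute-force suffix
sorting on 500 texts up to 2000 characters, exhaustive chain enumeration on
up to 8 anchors.  End-to-end round-trip checks cover n ∈ {10, 100} and root
lengths 100–10,000 at similarities 0.70–0.99, with the 10,000-base runs at
n = 10 — the package's desk-scale choice keeps every factor level covered
while the low-similarity long-sequence cells (where WFA's O(n·s) cost is
largest) stay small in n.

## Known limitations

- The center-star objective never refines the alignment between two
  non-center sequences; columns can be locally suboptimal between queries.
- Anchoring assumes near-unique exact matches exist; below ~75% identity few
  windows clear `l = 15` and most of each pair falls through to plain WFA,
  which is still exact but quadratic in the (now large) score.
- Memory for WFA traceback retains all wavefronts, O(s²); low-memory
  bidirectional variants are out of scope.
- No reverse-complement matching, no protein alphabets, no deduplication of
  identical inputs.
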