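# Methods

## Identity model

Two nucleotide sequences are compared through their maximal exact matches
(MEMs): exact matches that cannot be extended left or right without a
mismatch, an `N`, or a sequence boundary. Only MEMs of length ≥ `minlen`
are considered; the raw set is refined to segments with disjoint
projections on both sequences, each segment is extended outward under an
x-drop rule, and identity is summarized as

    eMEMi = Nmatch / Lquery ∈ [0, 1]

with `Nmatch` the matched-base count inside the extended segments (gap and
mismatch columns do not count) and `Lquery` the raw length of the shorter
sequence — always the query, because clustering processes sequences long to
short. The statistic deliberately ignores where on the longer sequence the
matches fall: a query fully contained in a longer genome scores 1.0.

Assumptions: input is DNA over `{A,C,G,T,N}`; `N` marks unknown sequence
and never matches anything, including another `N`, so assembly gaps cannot
contribute identity. Both-strand comparison evaluates the forward and
reverse-complement query independently and keeps the better strand;
strands are never pooled into one `Nmatch` sum, since pooling could count
palindromic loci twice.

## MEM enumeration with a sparse suffix array

The representatives are concatenated with per-sequence terminators and
indexed by a suffix array holding every `K`-th suffix (`K` = `sparse_k`,
default 1). Nucleotides are encoded in ASCII order (A<C<G<N<T); the
terminator after member *i* gets the distinct negative code `-(i+1)`, so
terminators sort below all nucleotides, all suffixes are distinct, and no
equality test can run across a sequence boundary. Terminator positions are
excluded from the sampled suffix set (such suffixes can never match a
pattern). Construction is numpy prefix-doubling — deterministic, ~O(n log n)
with small constants at the megabase scales targeted here; the LCP array is
computed by direct comparison of adjacent sampled suffixes.

For each query position, the window of length `tau = minlen - K + 1` is
located in the sampled array by binary search; every sampled suffix in the
interval is right-extended to its full match length, then verified for
left-maximality by scanning at most `K-1` characters leftward. A match is
emitted only from the *first* sampled reference position it contains, so
each MEM is reported exactly once and the reported set is provably
independent of `K` whenever `minlen ≥ K` (enforced; smaller `minlen`
raises an error rather than silently missing short MEMs). `tau` is the
standard sparse-matching bound: a MEM of length `len ≥ minlen ≥ K` contains
a sampled position at offset < `K`, leaving at least `minlen - K + 1`
matching characters to its right.

During clustering the collector also discards, before materializing them,
MEMs lying on indexed members shorter than the query, since only
representatives at least as long as the query are valid targets.

## Refinement geometry

Raw MEMs overlap and nest. Refinement proceeds:

1. remove MEMs whose representative *or* query span is contained in a
   single longer MEM's span (between equal-length MEMs with identical
   spans, the first in sort order survives);
2. remove MEMs covered by the union of their two flanking neighbours
   (neighbours in representative-start order; tested on both projections);
3. trim partial overlaps: right-to-left in representative-start order, a
   MEM overlapping its left neighbour on either sequence has its start
   shifted rightward on both sequences by the overlap amount; segments
   shrinking below one base are dropped. This sweep alternates with the
   identical sweep in query-start order until neither changes anything.

The alternation is the numerically delicate part: one representative-order
sweep alone cannot guarantee query-side disjointness when MEM order differs
between the two sequences (inversions, repeats), and a drop can expose a new
overlapping adjacency behind the sweep. Every trim strictly shrinks total
span length, so the alternation terminates; at its fixpoint, adjacent
disjointness in both sort orders implies pairwise disjointness of both
projections. For crossing (non-collinear) pairs the overlap amount
`left_end - cur_start` can exceed the true intersection, so conflicting
inverted segments are trimmed conservatively — eMEMi may undercount matched
bases in heavily rearranged pairs, never double-count.

## Extension

Each refined segment is extended left and right. Ungapped mode advances
both sequences in lockstep, tracking the running score (`match` +1,
`mismatch` −1 by default) and stopping when it falls `xdrop` (default 5)
below the best score seen; the best-scoring endpoint wins, with score ties
resolved toward the longer extension (more matched bases). Gapped mode
additionally runs a banded affine-gap x-drop dynamic program (`gap_open`
−2, `gap_extend` −1, three states, antidiagonal wavefront, cells pruned at
`xdrop` below the running best) and keeps whichever endpoint — gapped or
strictly diagonal — recovers more matched bases. Defining gapped extension
as the better of the two makes "gapped never recovers fewer matches, hence
never produces more clusters" a structural guarantee instead of an accident
of pruning order. Score parameters are configuration, not measurements:
they follow common seed-and-extend practice and are CLI-overridable.

Extensions are clipped at the midpoint of the gap to the neighbouring
segment on each projection independently (left neighbour gets
`gap - gap//2`, right neighbour `gap//2`), so extended projections stay
disjoint and Eq. eMEMi cannot double-count a base.

## Clustering

`filter_and_sort` drops sequences under `min_keep` (default 21 bp, matching
`minlen` — shorter sequences cannot contain a single seed) and sorts long to
short, ties broken by input order for reproducibility. Blocks are filled
greedily up to `chunk_mb` (default 400 Mbp) of text. Within a block, each
sequence is tested against the block's representatives in discovery order
and joins the *first* one reaching `memiden` (default 90%); the comparison
threshold uses a 1e-9 float cushion — eMEMi itself is a ratio of integers.
Representatives of equal length are valid targets (otherwise equal-length
exact duplicates could never cluster). After a block, a consolidated index
over its representatives screens every unassigned later sequence; these
screens are independent and thread-parallel, with assignments applied in
global rank order, so the result is identical for every thread count and
for every block partition.

The `rebuild` flag controls index maintenance inside a block: when on, new
representatives are folded into the block's main index every 64 promotions
(configurable); when off, never within the block. In both modes,
representatives promoted since the last build remain searchable through
small per-sequence indexes, so the flag affects speed only, never the
result.

## Synthetic data

`synth_data` generates i.i.d. uniform `{A,C,G,T}` sequences — the null
model under which the 21-bp seed default suppresses chance matches — and
plants redundancy by copying a representative (truncated to a random
75–95% prefix, so the representative is always the unique longest group
member) and mutating it with point substitutions and 1–3-bp indels to a
target identity; `indel_share` splits the mutation budget between the two.
Everything derives from one integer seed with no global random state.

What this emulates: controlled-identity redundancy with known truth, the
regime the identity statistic and greedy engine must get right. What it
does not: real genome features — repeat families, rearrangements,
horizontal transfer, compositional bias, real assembly gap structure.
Passing tests demonstrate algorithmic correctness on the stated model, not
clustering quality on any particular genome collection.

## Problem sizes and numerical checks

The test suite pins the MEM finder to a quadratic brute-force oracle over
1,000 random pairs (lengths ≤ 500, all `K` in 1–4, `L` in 5–25, both
strands), the refinement geometry over 10,000 random interval fixtures, the
ungapped extension against an exhaustive best-prefix-score scan, and the
chance-match null at full 1.7-Mbp scale over three fixed seed pairs.
`scripts/acceptance.py` reruns the null with five replicate pairs at
1.7 Mbp, minimum MEM length 15, sparse step 1, reporting the median of
per-replicate maxima; five replicates keep the median stable against the
~9% per-replicate chance of a 22-bp match. Benchmarks for the clustering properties use 6–20
groups of 2–4-kbp representatives — small enough for minutes-scale runs,
large enough that every planted copy carries hundreds of seeds.

## Known limitations

- Per-query-position binary search makes MEM scanning ~O(m · log n · tau)
  on random text but degrades toward quadratic on highly repetitive or
  near-duplicate megabase inputs (huge match intervals); the original
  suffix-link traversal strategies would be the upgrade path.
- eMEMi is asymmetric by design (containment scores 1.0) and conservative
  under heavy rearrangement (see refinement notes).
- Protein sequences, FASTQ, and alignment-format output are out of scope;
  the optional on-disk index dump is not implemented — indexes are always
  rebuilt in memory.
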