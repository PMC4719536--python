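# Methods

This document records what each stage of `bacpool` computes, the default
parameters and why they were chosen, and the numerical conventions that
affect results.

## Pool design (`bacpool.pools`)

Clones are nodes of an overlap graph; pools must be independent sets of a
fixed size (default 4).  Overlap edges are derived from physical-map
metadata by an **FPC adjacency proxy**: two clones overlap if they are
consecutive minimal-tiling-path entries in the same FPC contig
(`clone_graph_from_table`).  This is a conservative stand-in for true
clone-overlap coordinates, which FPC exports do not always carry.

`design_pools` runs a greedy partition over a seeded random clone order
and restarts (up to 1000 times) until every pool is edge-free.  If no
restart succeeds, it raises `PoolDesignError` carrying a greedily grown
clique as a witness of infeasibility.  The greedy strategy is exact for
edge-free inputs (384 clones always give 96 pools of 4) and in practice
succeeds quickly on sparse overlap graphs; it is not a completeness
proof, so an error means "no partition found", not "none exists" —
except that the attached clique, when larger than the pool size, is a
genuine certificate.

`expected_lane_coverage(yield_bp=40e9, n_bacs=384, unit_length=120_000)`
= 868.06x: one modern lane spreads over 96 pools of 4 BACs with ~870x
per clone, comfortably above the saturation plateau (below).

`compare_sizes_paired_t` is the closed-form paired *t* test
(`t = mean(d) / (sd(d)/sqrt(n))`, df = n−1, two-sided p from
`scipy.stats.t`); with 96 pools the df is 95.  Zero-variance edge cases
are defined explicitly: identical vectors give t = 0, p = 1; a constant
non-zero difference gives t = ±inf, p = 0.

## Read QC (`bacpool.readqc`)

Contaminant screening uses an **exact w-mer full-read match**: an index
of all w-mers (default w = read length) of the reference and its reverse
complement; a read matches if it occurs verbatim.  Exact matching is
appropriate because vector and *E. coli* contamination in a BAC library
is sequence-identical to its reference, and it makes recall on simulated
data exactly 100 % with zero false removals.  Pairs are removed
atomically (if either mate matches) since the mate of a contaminant read
is also contaminant.  Vector is checked before *E. coli* so a pair
matching both is accounted once, as vector.

Clonal-duplicate removal treats a pair as a duplicate of an earlier pair
if the canonical key `min((r1, r2), (revcomp(r2), revcomp(r1)))` has been
seen; the first occurrence is kept.  Note that at very deep coverage
this byte-identity rule also removes *coincidental* duplicates —
independent fragments with identical start and length — so the reported
clonal percentage slightly exceeds the true PCR-duplicate rate.  The
test suite checks the exact accounting identity (removed = pairs −
distinct keys) rather than a percentage band for this reason.

Coverage is `total_bases / (n_bacs × unit_length)` with
`unit_length = 120_000` (a typical BAC insert size) by default.

## Coverage saturation (`bacpool.saturation`)

Subsampling is **with replacement**: `n = ceil(cov × unit_length /
(2 × read_length))` pairs per coverage level, grid 200x–3000x in 100x
steps (29 levels; 11 clones → 319 assembly jobs).  Reads may be trimmed
to a fixed length first (`trim_to`).  Each (clone, level) draws from an
independent generator seeded `seed × 100003 + level_index` so levels are
reproducible independently.

**LOESS** is implemented from scratch (`loess_fit`): at each x₀ the
nearest `k = max(ceil(span·n), degree+1)` points by |x−x₀| are weighted
with the tricube kernel `(1 − (d/dmax)³)³` and a local polynomial
(default degree 2, span 0.75) is fit by weighted least squares on the
*centered* Vandermonde basis via `lstsq` on the sqrt-weighted system —
centering keeps the normal equations well-conditioned at large x.  If
the local design is rank-deficient the fit falls back to degree 1 with a
`RuntimeWarning`.  The implementation is verified against a brute-force
normal-equations oracle to 1e−8 relative accuracy.

The **plateau** (`find_plateau`) is the smallest coverage whose fitted
value is at least `(1 − epsilon) × max(fitted)` within a window (default
200x–1000x, epsilon = 0.01).  Epsilon is monotone: stricter epsilon gives
a later plateau.  On a toy 10 kb clone with the bundled unitig assembler
the curve saturates at ≥ 99 % of the true length.

## Deconvolution (`bacpool.deconvolve`)

Each BES is aligned to the pooled assembly; every hit is scored

```
S = b − d_s,   d_s = min(subject_start, contig_length − subject_end)
```

where `b` is the bit score and `d_s` the distance of the aligned segment
from the nearer contig end.  The edge-distance penalty encodes the prior
that a true BES lands at a contig terminus; an equally strong alignment
in the middle of a contig is more likely a repeat.  The winner is chosen
by the sort key `(−S, −b, d_s, subject_id)` — ties on S break toward the
higher raw bit score, then the smaller edge distance, then
lexicographically smallest contig, making assignment fully deterministic.

Length filter: Sanger BES participate only if
`120 < length < max_length`; short reads carry too little signal and
very long "reads" are typically concatenation artifacts.  The upper
bound is configurable with **default 1000 bp** (an unconstrained ceiling
would admit obvious artifacts; 1000 bp comfortably exceeds real Sanger
read lengths).  120 bp **vector-end proxies** — the vector sequence
flanking the cloning site, used when a clone lacks usable BES — bypass
the length filter by design; they are exactly 120 bp by construction.

A clone is *anchored* when both its forward and reverse BES are assigned;
conflicting assignments (two clones' BES claiming one contig end) are
reported, not silently resolved.  `pair_pool_to_singletons` matches
pooled contigs to singleton assemblies by summed bit score, requiring
≥ 50 % of the query aligned (union of hit intervals) and declaring a tie
when the runner-up is within 20 % of the winner.

## Mate-pair QC and links (`bacpool.matepair`)

Orientation classes follow the outward-facing library convention: for
the two mates ordered by leftmost mapping position, **RF** (leftmost on
the minus strand, rightmost on plus) is correct; FR and FF/RR indicate
artifacts.  The insert size is the **outer distance** — rightmost end
minus leftmost start — matching how outward-facing libraries are sized.

Validation pairs require unique hits, 100 % identity and read length
> 100 bp for both mates, mapped to the same contig.  Scaffolding pairs
require 100 % identity over the *full* read length and both contigs in
the same pool.  `write_sspace_tab` emits the 6-column tab file with
1-based inclusive coordinates.

`bundle_links` groups inter-contig links by the unordered contig pair
plus mate strands, keeps bundles with at least **K = 10** links, and
estimates the gap as the median of `insert_midpoint − (outward coverage
on both sides)`, where the outward coverage of a mate is `contig_length
− start` for a minus-strand mate and `end` for a plus-strand mate.  The
midpoint of the allowed insert range stands in for the unknown true
insert of each pair, so the estimate is unbiased only when the selected
spanning pairs are not strongly length-biased — use a narrow
`insert_range` when the library is tight.  On simulated data with a
6–7 kb library the estimate is within tens of bp of a 500 bp truth gap.

## Simulator (`bacpool.simulate`)

What it emulates: mosaic BAC inserts (per-clone libraries of 3 kb repeat
units, copies diverged by 1 % substitutions, one truncated final copy so
the repeat fraction is hit exactly); terminal 600 bp BES with 0.1 %
error; paired-end reads with normal insert sizes; contaminant reads from
a ~50 kb *E. coli* proxy and a ~7.5 kb vector proxy that are 32-mer
disjoint from every insert (so exact screening is truth-faithful);
clonal duplicates copied from already-drawn insert pairs; mate-pair
libraries with uniform 6–10 kb inserts and an orientation mix (default
99 % RF / 0.3 % FR / 0.7 % FF-RR).  Contaminant fractions are fractions
of the final total (defaults 12 % *E. coli*, 4 % vector, 0.6 % clonal)
realized by deterministic rounding; every pair carries a truth label.

What it does **not** emulate: sequencing base-call errors on Illumina
reads, quality-score distributions, GC-coverage bias, chimeric reads,
heterozygosity, and genuine biological repeat families — repeats are
clone-local.  These omissions are deliberate: the suite needs exact
ground truth for filter recall and deconvolution accuracy, not a
realistic error model.

All randomness flows through `numpy.random.default_rng(seed)`; results
are bit-reproducible for a given seed and library version.

## Problem sizes used in testing

Unit tests run on pools of 2–4 clones of 6–10 kb with the bundled toy
de-Bruijn unitig assembler (k = 21).  The acceptance checks use ~1.2 ×
10⁵ ground-truthed read pairs for filter exactness, 10 pools × 4 clones
× 60 kb (80 BES) for deconvolution recovery, 5 × 10⁴ mate pairs for
classification closure, and 100 random LOESS instances against the
brute-force oracle.

## Limitations

- The overlap graph from FPC metadata is an adjacency proxy; with true
  overlap coordinates, fewer edges (hence easier pooling) would result.
- The greedy pool designer is a heuristic; infeasibility is certified
  only when the witness clique exceeds the pool size.
- Exact-match contaminant screening assumes contamination is
  sequence-identical to its reference; diverged contaminants need an
  aligner-based screen upstream.
- Gap estimates assume the insert-range midpoint; wide or skewed
  libraries bias the estimate (see above).
- The toy assembler bundled with the tests is for verification only and
  is not a substitute for a production assembler; the CLI accepts an
  external assembler command for real data.
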