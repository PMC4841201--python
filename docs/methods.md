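# Methods

## The usage-deviation model

For a word *W* of length *k* the toolkit computes the ratio of its observed
count to its expectation under a zero-order Markov (mononucleotide shuffle)
model,

TUD(*W*) = *N*(*W*) / *E*(*W*),  *E*(*W*) = *A*^a · *T*^t · *C*^c · *G*^g · *N*,

with all quantities taken over the genome **extended by its reverse
complement**. Extension makes the statistic strand-independent: every
occurrence of *W* on one strand is an occurrence of its reverse complement
on the other, so TUD(*W*) = TUD(revcomp *W*) holds bit-exactly. The
implementation preserves this identity deliberately — extended counts of
complementary bases are equal integers, so *A* = *T* and *C* = *G* as
floats, and `expected_count` multiplies the A/T and C/G factors in a fixed
grouping so complementary words evaluate to the identical float.

The two strands are kept as separate strings; no window spans the
forward/reverse junction, which would count artifactual words.

Assumptions and conventions:

- **N in E(W)** is the extended sequence length (both strands). An
  alternative reading — the number of word start positions,
  2·(L − k + 1) — differs by a factor of order k/L (≈ 10⁻⁴ for a typical
  phage genome) and is available as
  `expected_denominator="positions"`.
- **Ambiguity codes** are mapped to N on input; any counting window that
  touches an N is skipped, and composition is computed over A/C/G/T
  characters only. The statistic is therefore defined on the unambiguous
  part of the sequence.
- **Unobserved words** get deviation 0 rather than NaN so vectors remain
  distance-ready; words that are unobserved in *any* genome of a
  collection are removed by the universality filter before distances or
  log transforms, which also guarantees strictly positive inputs to the
  PCA log.
- **Canonicalization** keeps the lexicographically smaller of each
  reverse-complement pair (136 of 256 tetranucleotides: 120 pairs + 16
  palindromes), removing the exact redundancy that extension creates.
- k is capped at 8 (4⁸ = 65 536 words) to bound memory; the interesting
  regimes are k ∈ {2..7}.

## Between-genome comparison

Distances are Euclidean over the shared (canonical, filtered) word list.
Two tree builders consume the distance matrix:

- **Neighbor joining** (Saitou–Nei), written in-package: Q-matrix
  selection, standard branch-length formulas, final three-taxon resolution
  by the three-point formulas. On tree-additive matrices the generating
  topology and branch lengths are recovered exactly (verified against
  path-sum oracles and an independent implementation). Negative
  branch-length estimates are clamped to zero with the deficit moved to the
  sister branch, so the pair still sums to its joining distance. Output is
  unrooted (trifurcating root). Ties in the Q-matrix resolve to the first
  minimum in row-major order, making results deterministic in input order.
- **UPGMA / average linkage**: unweighted average of inter-cluster
  distances, merge height d/2, producing a rooted ultrametric dendrogram.
  Ties are broken by the lexicographically smallest pair of cluster labels
  (a cluster labeled by its smallest member id) for platform-independent
  determinism. On exactly ultrametric input the cophenetic distances
  reproduce the matrix to 1e-9 (checked against an independent
  average-linkage implementation).

**PCA** uses a natural-log transform (base choice only rescales loadings
uniformly; fixed for reproducibility), column centering, no column scaling,
and SVD. Variance fractions come from squared singular values; component
signs are fixed so each loading column's largest-magnitude entry is
positive. Centered data are reproduced by scores · loadingsᵀ to 1e-9.

**Monophyly** of a labeled group means some edge of the unrooted tree
separates exactly that group's leaves; the check compares the group's leaf
set (and its complement) against all clades, which enumerates every edge's
bipartition, and is verified against a graph-severing oracle.

## Within-genome scanning

Windows are 0-based half-open, 2000 bp with 500 bp step by default — wide
enough to sample most of the 256-word space, narrow enough to localize a
few-kb anomaly. A trailing partial window is dropped (a short window
under-samples the word space); only when the genome is shorter than one
window is a single truncated window used. Each window is extended by its
own reverse complement and normalized to its own composition, so a window
vector is exactly the whole-genome statistic applied to the window
subsequence (the tests assert bit-identity).

Window-window distances use canonicalized vectors restricted, per pair, to
words with nonzero expectation in both windows — a word rendered
unattainable by a missing nucleotide should not contribute distance.
Entries between physically overlapping windows are masked
(|Δstart| < window size) and excluded from all statistics.

The **outlier caller** summarizes each window by its mean distance to all
non-overlapping windows and flags windows at or above
median + z · 1.4826 · MAD (z = 3 by default). The robust location/scale
pair tolerates the heavy upper tail that genuine inserts and repeat blocks
create; the 1.4826 factor scales the MAD to an SD-equivalent under
normality. `≥` (rather than `>`) keeps the z = 0 degenerate case sensible
(at least half the windows flag). Adjacent flagged windows merge into
0-based half-open intervals. At least 5 unmasked pairs are required.

**Word tracks** profile a single word (default 5000 bp / 1000 bp step, the
regime that exposes genome-wide shifts in e.g. GATC usage): per window,
occurrences over both strands (overlapping matches counted) divided by the
window's zero-order expectation. Group-mean tracks average member tracks by
window index from the genome start, truncating at the shortest genome —
the member genomes are unaligned, and window index is the only common
coordinate.

## Synthetic data

The generator emulates the structure the comparison methods are meant to
recover, not real phage biology (no gene content, no realistic length or
GC distributions):

- **Clusters** are order-3 Markov models — the lowest order that directly
  shapes 4-mer usage — drawn per context from a Dirichlet with
  concentration 1/bias_strength around uniform. `bias_strength` (default
  0.5) controls how idiosyncratic a cluster's word usage is;
  0 is exactly uniform, and separation between clusters grows monotonely
  with it.
- **Within-cluster spread** comes from re-drawing each member's model from
  a tight Dirichlet (concentration 500) around the cluster model, so
  members are similar but not identical.
- **Planted HGT**: a segment generated from a *different* cluster's model
  replaces host sequence at a recorded position (length preserved, exact
  ground-truth coordinates). **Planted repeats**: a tandem block
  (unit × copies) is inserted, growing the genome.
- **Determinism**: one top-level seed; sub-seeds for every model, genome
  and planted feature derive by fixed integer arithmetic mod 2³¹, so the
  same spec yields byte-identical FASTA and partial regeneration is stable.

Passing recovery tests on these communities shows the statistics separate
genuinely distinct word-usage processes at realistic genome sizes; it does
not show performance on real genomes, where amelioration, shared ancestry
and mosaicism blur the signal.

## Problem sizes and numerical choices

Test and acceptance workloads are sized so each stochastic check is a
≥ 2.5σ statement rather than a coin flip: single-word track calibration
uses a 1 Mb i.i.d. genome (a lone palindromic 4-mer has ~2% sampling SD
there, vs ~5% at 100 kb), empirical transition-frequency validation uses
500 kb (~8 000 visits per context), and community recovery uses the
default study conditions (3 clusters × 5 genomes × 50 kb, bias 0.5,
20 seeds). Heatmap separation between planted and homogeneous genomes is
tested as a ratio between the two conditions, because at 2 kb windows
word-sampling noise sets the scale of the median distance.

## Known limitations

- The zero-order expectation ignores lower-order correlations; first- or
  second-order normalizations are out of scope.
- The outlier caller flags *any* compositional anomaly — repeat blocks and
  genuine transfers look alike; distinguishing them needs repeat discovery
  or homology search, which this package does not do.
- Ameliorated (old) transfers converge to the host signature and are
  invisible by construction.
- Group-mean tracks align genomes by window index only; genomes of very
  different architecture make the mean hard to interpret.
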