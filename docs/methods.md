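# Methods

## The structure

Let `T0` be the set of canonical k-mers of a read set (`N = |T0|`), the
node set of the de Bruijn graph used in assembly. The cascade is a
sequence of Bloom filters `B1..Bt` plus a sorted array `T_t`:

- `B1` stores `T0`.
- `T1` (*critical false positives*) = potential neighbors of `T0`
  members that `B1` reports present but are not in `T0`. These are the
  only false positives reachable by a traversal, which by construction
  only queries the ≤8 k-mers overlapping a known node by k−1 letters.
- For `i ≥ 2`: `B_i` stores `T_{i−1}`, and `T_i = {u ∈ T_{i−2} : u ∈
  B_i}` — the members of the grandparent level wrongly captured by
  `B_i`. Hence `T0 ∩ T1 = ∅`, `T0 ⊇ T2 ⊇ T4 ⊇ …`, `T1 ⊇ T3 ⊇ T5 ⊇ …`.

A query probes filters in order. If the first *no* occurs at filter
`i+1`, the answer is *yes* iff `i` is odd. If all `t` filters say yes,
the residual decides: `T_t ⊆ T0` for even `t` (found ⇒ member), `T_t ⊆
T1` for odd `t` (found ⇒ non-member). Under the traversal contract the
answer equals exact set membership — the test suite asserts 100%
agreement with a brute-force oracle on every contract-valid probe for
`t ∈ {1,2,4}` and several k. Outside the contract (a random k-mer that
is no node's potential neighbor) answers are best-effort only; making
them exact would require storing all false positives and is explicitly
out of scope.

Construction is off-line (insertion after build is not supported):
candidate generation queries all 8 extensions of every `T0` member
against `B1`, deduplicates, and removes `T0` members by sorted-array
set difference. An optional partitioned mode runs candidate generation
and the difference in chunks, spilling survivors to scratch files — the
desk-scale mirror of the external-memory construction needed at genome
scale. `T_t` is kept as a sorted packed array searched by binary
search rather than a hash table.

## Parameters

- `k` (k-mer length, bases): 1–64. Codes pack 2 bits/base; `k ≤ 31`
  runs vectorized on uint64 arrays, `k ≥ 32` through an equivalent
  scalar path on Python ints (tested for agreement). Canonical form =
  min(word, reverse complement) under A<C<G<T, which makes integer
  comparison equal lexicographic comparison.
- `t` (number of filters): default 4. Memory improves marginally beyond
  `t = 6`; query cost grows with `t·r` hash evaluations, but >99% of
  traversal queries resolve within four filters.
- `r` or `r1..rt` (bits per stored element): default is the
  memory-optimal single ratio for `(t, k)` from the estimator (e.g.
  5.874 for k=21, t=4). For `t = 1` the convention is the single-filter
  baseline ratio `1.44·log2(16k/2.08)` (8-extension estimate), matching
  the method the cascade is benchmarked against; `t ≥ 2` uses the
  6-extension model.
- `d` (abundance cutoff): k-mers occurring *more than* `d` times are
  kept, i.e. inclusive minimum count `d+1` (the CLI flag `--min-count`
  is the inclusive form). Default d=2 in the simulation config, suited
  to ~50x coverage with ~1% errors.
- `p` (hash functions per filter): `max(1, round(r ln 2))`. The
  analysis uses the real-valued optimum; the integer rounding changes
  the FP rate by well under the test tolerances (e.g. at r=6.049:
  0.0548 realized vs 0.0547 modeled).
- master seed: one 64-bit seed determines all per-filter hash seeds;
  identical seeds and inputs give bit-identical structures.

## Numerical and design choices

- `c = 0.6185` is fixed at its conventional printed value (not
  recomputed as `(1/2)^ln2 ≈ 0.61850…`) so model tables are
  reproducible to the digit.
- All ratio optimizations are bounded below by `R_MIN = 1/ln 2 ≈
  1.4427`: below it the optimal hash count drops under 1 and `F ≈ c^r`
  no longer describes a realizable filter. This bound is load-bearing
  for the per-filter-ratio infinite model, whose unconstrained infimum
  (≈7.90 as tail ratios → 0) is an artifact of the model leaving its
  validity region; with the bound the minimum is 7.93 bits at `r1 ≈
  4.41` with all later ratios on the bound.
- Scalar minimization is bounded Brent with `xatol = 1e-9`; vector
  minimization is multi-start L-BFGS-B from a fixed grid of starts.
  Both are deterministic. The vector objective is near-flat around its
  minimum, so the minimized *bits* value is the reproducible quantity,
  not the argmin vector. Notably, for `k ≥ 64` at `t = 4` the optimizer
  finds operating points a few hundredths of a bit below the
  conventionally cited vectors (e.g. 8.430 vs 8.512 at k=64) — the
  cited vectors are near-optimal but not minima of the expression; the
  tests therefore require the optimizer to match-or-beat them rather
  than reproduce them.
- Hashing: a splitmix64-style finalizer over the packed code (hi/lo
  folded for >64-bit codes) with double hashing `h_i = a + i·b mod m`,
  `b` forced odd. Bitmap sizes are plain `round(r·n)` with modulo
  reduction — no primality or power-of-two constraint. Empirical FP
  rates match `(1−e^{−p/r})^p` within 3 binomial σ at r ∈ {4, 8, 12}.
- Degenerate cases: an empty level yields a 1-bit all-zero filter and
  all deeper levels empty; palindromic k-mers (even k) are stored once
  and their colliding extensions deduplicated; `n = 0` filters answer
  *no* to everything.
- Query accounting: the level that answers *no* "resolves" a query;
  queries passing all filters are attributed to the residual table.
  The traversal issues all 8 potential-neighbor queries per node
  without deduplication by default (an optional dedup mode collapses
  palindromic collisions), and iterates the stored node set rather than
  walking edges — the 8-queries-per-node model depends only on the
  visit multiset, and edge-walking would require tip/branch policy the
  membership structure does not define.

## Synthetic data

`bloomcascade.simulate` generates uniform i.i.d. random genomes and
fixed-length reads placed uniformly on either strand with i.i.d.
substitution errors (constant FASTQ quality, since qualities are
ignored). Defaults — 100 bp reads, 50x coverage, 1% error, d=2, k=21 —
emulate a small high-coverage bacterial-style experiment. The model
tests use genome-derived k-mer sets (path graphs) because the "2 of 8
extensions are real" assumption behind the `6Nc^r` and query models
holds for path-like node sets, not for i.i.d. random k-mer sets.

What synthetic data does *not* emulate: genomic repeat structure and
word-frequency bias (random genomes have almost no repeated k-mers, so
branching nodes are essentially absent), realistic error profiles
(indels, quality-correlated errors), paired reads, and contamination.
Passing tests therefore demonstrate the correctness and calibration of
the *data structure* — exactness under the contract, level-size decay,
query distribution — not robustness of any downstream assembly
pipeline. Structure sizes and query statistics measured on synthetic
path graphs (~8.6 bits/k-mer at k=21, t=4; ~71%/24%/4%/1.3%/0.3%
per-level resolution) sit where the analytical model puts them, and the
model is the same one that describes real read sets of comparable N.

Problem sizes in the default test run are desk-scale by design: exact
membership on 10⁴-node builds, stochastic calibration on a 10⁵-node
path graph, Monte-Carlo FP estimation with 10⁵ probes. These sizes put
binomial sampling error well below the asserted tolerances while the
whole suite stays fast.

## Known limitations

- In-memory counting only (hash map / array sort); no streaming
  external-memory k-mer counter. The partitioned build mode bounds peak
  memory of the set-difference step only.
- No online insertion; the construction is inherently off-line.
- No assembly operations (contigs, unitigs, branching-node marking) —
  the structure answers membership and neighbor queries only.
- k > 64 is not supported (codes capped at 128 bits).
- Out-of-contract queries carry the underlying filters' false-positive
  rate; this is a property of the approach, not an implementation gap.
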