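# bloomcascade

Exact, memory-efficient membership for de Bruijn graphs via **cascading
Bloom filters**.

Genome assemblers and many other NGS tools are built on the de Bruijn
graph: nodes are the distinct k-mers of a read set, arcs join k-mers
overlapping by k−1 letters. At hundreds of millions to billions of
nodes, how compactly the node set can be stored decides whether an
assembly fits in memory. A single Bloom filter is compact but lies
(false positives); storing its *critical false positives* — the
potential neighbors of true nodes wrongly reported present — restores
exactness for graph traversal, because a traversal only ever queries
potential neighbors of known nodes. This package implements the
recursive refinement of that idea: represent the critical false
positives `T1` by a second Bloom filter `B2`, whose "false false
positives" `T2 ⊆ T0` feed `B3`, and so on, truncating at level `t` with
a small sorted residual table `T_t`.

## The model

With `N = |T0|` nodes, a filter of `r` bits per element and `p = r ln 2`
hash functions has false-positive rate `F ≈ c^r`, `c = 0.6185`. Since
about 2 of each node's 8 potential neighbors are real nodes, `|T1| ≈
6Nc^r`, `|T2| ≈ Nc^r`, `|T3| ≈ 6Nc^2r`, … The memory of the infinite
cascade is

```
r + 6rc^r + rc^r + 6rc^2r + …  =  (1 + 6c^r) · r / (1 − c^r)   bits/k-mer,
```

minimized at **8.45 bits/k-mer** for `r = 5.464` — versus
`1.44·log2(16k/2.08) + 2.08` (12–16 bits, growing with k) for the
single-filter approach. Truncation at `t = 4` filters already achieves
8.66 bits at `k = 32`, and per-filter ratios `r1..rt` (chain-accumulated
exponents) shave a few percent more. Queries probe `B1, B2, …` until the
first *no* at level `i+1`; the answer is *yes* iff `i` is odd, and the
sorted residual table decides the <1% of queries that pass every filter.
Membership answers are **exact** under the traversal contract.

## Worked example

```python
from bloomcascade import build, count_kmers, encode
from bloomcascade.simulate import random_genome, simulate_reads

genome = random_genome(20_000, seed=7)
reads = simulate_reads(genome, read_length=100, coverage=50, error_rate=0.01, seed=8)
t0 = count_kmers(reads, k=21, d=2)   # keep k-mers seen more than twice
g = build(t0, t=4)                   # memory-optimal ratios for (k=21, t=4)
print(g.report())
```

prints

```
cascading Bloom filter: k=21, t=4, N=20175
  |T0| = 20175
  |T1| = 7268
  |T2| = 1204
  |T3| = 436
  |T4| = 72
  B1: m = 118505 bits (r = 5.874)
  B2: m = 42691 bits (r = 5.874)
  B3: m = 7072 bits (r = 5.874)
  B4: m = 2561 bits (r = 5.874)
  T4 table: 3024 bits (72 k-mers)
  total: 173853 bits = 8.617 bits/k-mer
```

The level sets shrink geometrically (20175 → 7268 → 1204 → 436 → 72), so
the whole exact structure costs 8.62 bits/k-mer — where a single filter
plus explicit false-positive list needs ~12.6 bits at this k. Querying
is exact: `g.query(encode(genome[1000:1021]))` is `True`, a foreign
k-mer answers `False`, and `g.neighbors_in_graph(u)` returns the true
graph neighbors (2 for interior path nodes). An exhaustive traversal
(`bloomcascade.traverse`) reproduces the analytical query distribution:
at `r = 6.049`, 70.9% of queries are resolved by `B1`, 23.6% by `B2`,
and only 0.3% reach the residual table.

More narrative scripts live in `examples/`. A thin CLI wires the same
library functions for shell use:

```
bloomcascade simulate --length 100000 --coverage 50 --out-reads r.fq
bloomcascade count r.fq --k 21 --min-count 3 --out k.kmr
bloomcascade build k.kmr --t 4 --out g.cdbg
bloomcascade traverse-stats --structure g.cdbg --kmers k.kmr
bloomcascade estimate --k 32 --t 4
```

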