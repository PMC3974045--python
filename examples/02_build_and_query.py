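"""Build a cascade from synthetic reads and query it.

Simulates a small sequencing experiment (50x coverage, 1% substitution
errors), counts canonical 21-mers keeping those seen at least 3 times,
builds the 4-filter cascade, and queries a few k-mers. Membership
answers are exact for any k-mer that is a node or a potential neighbor
of a node — the only k-mers a graph traversal ever asks about.
"""

from bloomcascade import build, count_kmers, encode
from bloomcascade.simulate import random_genome, simulate_reads

genome = random_genome(20_000, seed=7)
reads = simulate_reads(genome, read_length=100, coverage=50, error_rate=0.01, seed=8)
t0 = count_kmers(reads, k=21, d=2)  # keep k-mers seen more than twice
print(f"{len(reads)} reads -> {len(t0)} distinct canonical 21-mers\n")

g = build(t0, t=4)  # ratios default to the memory-optimal r for (k=21, t=4)
print(g.report())

probe_in = genome[1000:1021]
probe_out = "A" * 21
print(f"\nquery {probe_in}: {'yes' if g.query(encode(probe_in)) else 'no'} (a genome k-mer)")
print(f"query {probe_out}: {'yes' if g.query(encode(probe_out)) else 'no'} (not in the genome)")

u = encode(genome[5000:5021])
nbrs = g.neighbors_in_graph(u)
print(f"\n{u} has {len(nbrs)} graph neighbors (interior path nodes have 2)")
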