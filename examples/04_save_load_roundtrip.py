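"""Persist a structure to disk and reload it bit-exactly.

The on-disk format stores the t Bloom filter bitmaps and the packed,
sorted residual table with per-component checksums; a reloaded
structure answers every query identically.
"""

import tempfile
from pathlib import Path

import numpy as np

from bloomcascade import CascadingDBG, build, count_kmers
from bloomcascade.kmers import neighbor_matrix
from bloomcascade.simulate import random_genome

t0 = count_kmers([random_genome(5_000, seed=3)], k=21, d=0)
g = build(t0, t=2)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "graph.cdbg"
    g.save(path)
    print(f"saved {path.stat().st_size} bytes "
          f"({g.bits_used()['bits_per_kmer']:.2f} bits/k-mer in memory)")
    h = CascadingDBG.load(path)

probes = neighbor_matrix(t0.codes, t0.k).ravel()[:1000]
a, _ = g.query_many(probes)
b, _ = h.query_many(probes)
print(f"queries identical after round-trip: {bool(np.array_equal(a, b))}")
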