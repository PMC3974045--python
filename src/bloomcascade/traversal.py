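"""Exhaustive-traversal query statistics.

Visits every true node of the graph exactly once and issues the full
8-potential-neighbor query pattern against the cascade, recording which
level (filter 1..t, or the residual table) resolves each query. This is
the empirical counterpart of the analytical query-distribution model:
on a long path-like node set the per-level fractions should track
``(6-6c^r)/8, (2-2c^r)/8, (6c^r-6c^2r)/8, …``.

Because the query-count model depends only on the multiset of visited
nodes (8 queries each), the traversal iterates the stored node set
directly rather than walking edges; the report is invariant to
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import CascadingDBG, QueryStats
from .kmers import KmerSet, neighbor_matrix

__all__ = ["TraversalReport", "traverse"]


@dataclass
class TraversalReport:
    nodes_visited: int
    total_queries: int
    stats: QueryStats
    yes_queries: int

    @property
    def fractions(self) -> list[float]:
        """Resolved fraction per filter level, then the residual table."""
        return self.stats.fractions()

    @property
    def yes_fraction(self) -> float:
        return self.yes_queries / self.total_queries if self.total_queries else 0.0

    def to_dict(self) -> dict:
        return {
            "nodes_visited": self.nodes_visited,
            "total_queries": self.total_queries,
            "resolved_per_level": list(self.stats.per_level),
            "resolved_residual": self.stats.residual,
            "fractions": self.fractions,
            "yes_fraction": self.yes_fraction,
        }


def traverse(g: CascadingDBG, t0: KmerSet, dedup: bool = False) -> TraversalReport:
    """Query all 8 potential neighbors of every ``T0`` member once.

    With ``dedup`` the <= 8 neighbors of each node are deduplicated
    before querying (palindromic or self-overlapping extensions can
    coincide); the default keeps all 8, matching the model's
    8-queries-per-node accounting.
    """
    if t0.k != g.k:
        raise ValueError(f"k mismatch: structure k={g.k}, k-mer set k={t0.k}")
    nbrs = neighbor_matrix(t0.codes, t0.k)  # (n, 8)
    if dedup:
        rows = np.sort(nbrs, axis=1)
        keep = np.ones_like(rows, dtype=bool)
        keep[:, 1:] = rows[:, 1:] != rows[:, :-1]
        queries = rows[keep]
    else:
        queries = nbrs.ravel()
    stats = QueryStats()
    answers, _ = g.query_many(queries, stats=stats)
    return TraversalReport(
        nodes_visited=len(t0),
        total_queries=len(queries),
        stats=stats,
        yes_queries=int(answers.sum()),
    )
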