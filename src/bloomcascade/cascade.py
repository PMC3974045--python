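"""Cascading Bloom filter representation of a de Bruijn graph.

The node set ``T0`` (canonical k-mers of the reads) goes into a Bloom
filter ``B1``. Its *critical false positives* ``T1`` — potential
neighbors of ``T0`` members that ``B1`` wrongly reports present — are
the only false positives a graph traversal can ever see, so storing
them restores exactness. Instead of storing ``T1`` explicitly, the
structure recurses: ``B2`` stores ``T1`` and its "false false
positives" ``T2`` (members of ``T0`` wrongly in ``B2``) feed ``B3``,
and so on; generally ``B_i`` stores ``T_{i-1}`` and ``T_i = {u in
T_{i-2} : u in B_i}``. The level sets satisfy ``T0 ∩ T1 = ∅``,
``T0 ⊇ T2 ⊇ T4 ⊇ …`` and ``T1 ⊇ T3 ⊇ T5 ⊇ …``.

A membership query probes ``B1, B2, …`` until the first ``B_{i+1}``
answering *no*; the answer is *yes* exactly when ``i`` is odd. The
cascade is truncated at level ``t``: the residual set ``T_t`` is kept
as a sorted array (binary search decides queries that pass every
filter). Under the traversal contract — queried k-mers are members of
``T0`` or potential neighbors of members — answers are exact; outside
the contract they are best-effort only.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import estimator
from ._bits import derive_seed
from .bloom import DEFAULT_SEED, BloomFilter, make_filter
from .kmers import Kmer, KmerSet, neighbor_matrix

__all__ = ["CascadingDBG", "QueryStats", "build"]

_MAGIC = b"CDBG"
_VERSION = 1


@dataclass
class QueryStats:
    """Per-level accounting of which filter resolved each query."""

    per_level: list[int] = field(default_factory=list)  # resolved by B_1..B_t
    residual: int = 0  # decided by the sorted T_t table

    @property
    def total(self) -> int:
        return sum(self.per_level) + self.residual

    def fractions(self) -> list[float]:
        tot = self.total
        if tot == 0:
            return [0.0] * (len(self.per_level) + 1)
        return [c / tot for c in self.per_level] + [self.residual / tot]


class CascadingDBG:
    """Filters ``B1..Bt`` plus the sorted residual table ``T_t``."""

    def __init__(
        self,
        k: int,
        filters: Sequence[BloomFilter],
        residual: np.ndarray,
        ratios: Sequence[float],
        n_true: int,
        level_sizes: Optional[Sequence[int]] = None,
        master_seed: int = DEFAULT_SEED,
    ):
        if len(filters) < 1:
            raise ValueError("need at least one Bloom filter (t >= 1)")
        self.k = int(k)
        self.t = len(filters)
        self.filters = list(filters)
        self.residual = np.asarray(residual)
        self.ratios = [float(r) for r in ratios]
        self.n_true = int(n_true)
        self.level_sizes = list(level_sizes) if level_sizes is not None else None
        self.master_seed = int(master_seed)

    # -- queries -----------------------------------------------------------

    def _check_k(self, k: int) -> None:
        if k != self.k:
            raise ValueError(f"k mismatch: structure has k={self.k}, query has k={k}")

    def _residual_contains(self, code: int) -> bool:
        i = np.searchsorted(self.residual, code)
        return i < len(self.residual) and int(self.residual[i]) == int(code)

    def query(self, u: Union[Kmer, int], stats: Optional[QueryStats] = None) -> bool:
        """Exact membership of ``u`` in ``T0`` under the traversal contract.

        Probes the filters in order; the first level ``j`` with ``u not
        in B_j`` corresponds to ``i = j - 1`` of the parity rule, so the
        answer is *yes* iff ``j`` is even. If every filter says yes the
        residual decides: ``T_t`` is a subset of ``T0`` for even ``t``
        (found => member) and of ``T1`` for odd ``t`` (found => false
        positive, i.e. non-member).
        """
        if isinstance(u, Kmer):
            self._check_k(u.k)
            code = u.code
        else:
            code = int(u)
        if stats is not None and not stats.per_level:
            stats.per_level = [0] * self.t
        for j, f in enumerate(self.filters, start=1):
            if not f.contains(code):
                if stats is not None:
                    stats.per_level[j - 1] += 1
                return j % 2 == 0
        if stats is not None:
            stats.residual += 1
        found = self._residual_contains(code)
        return found if self.t % 2 == 0 else not found

    def query_many(self, codes: np.ndarray, stats: Optional[QueryStats] = None):
        """Vectorized :meth:`query`: returns (answers, resolving level).

        ``levels[i]`` is 1..t for queries resolved by a filter and 0 for
        queries decided by the residual table.
        """
        codes = np.asarray(codes)
        n = len(codes)
        answers = np.zeros(n, dtype=bool)
        levels = np.zeros(n, dtype=np.int64)
        alive = np.arange(n)
        for j, f in enumerate(self.filters, start=1):
            if len(alive) == 0:
                break
            cont = f.contains_many(codes[alive])
            resolved = alive[~cont]
            answers[resolved] = j % 2 == 0
            levels[resolved] = j
            alive = alive[cont]
        if len(alive):
            if len(self.residual):
                idx = np.searchsorted(self.residual, codes[alive])
                idx = np.minimum(idx, len(self.residual) - 1)
                found = self.residual[idx] == codes[alive]
            else:
                found = np.zeros(len(alive), dtype=bool)
            answers[alive] = found if self.t % 2 == 0 else ~found
        if stats is not None:
            counts = np.bincount(levels, minlength=self.t + 1)
            if not stats.per_level:
                stats.per_level = [0] * self.t
            for j in range(1, self.t + 1):
                stats.per_level[j - 1] += int(counts[j])
            stats.residual += int(counts[0])
        return answers, levels

    def neighbors_in_graph(self, u: Kmer) -> list[Kmer]:
        """True graph neighbors of a ``T0`` member: the potential
        neighbors for which :meth:`query` answers yes (exact under the
        contract; at most 8)."""
        from .kmers import potential_neighbors

        self._check_k(u.k)
        return [v for v in potential_neighbors(u) if self.query(v)]

    # -- reporting ----------------------------------------------------------

    def bits_used(self) -> dict:
        """Actual storage footprint per component, in bits."""
        filt = [f.m for f in self.filters]
        resid = 2 * self.k * len(self.residual)
        total = sum(filt) + resid
        return {
            "filters": filt,
            "residual": resid,
            "total": total,
            "bits_per_kmer": total / self.n_true if self.n_true else float("nan"),
        }

    def report(self) -> str:
        b = self.bits_used()
        lines = [f"cascading Bloom filter: k={self.k}, t={self.t}, N={self.n_true}"]
        if self.level_sizes is not None:
            lines += [
                f"  |T{i}| = {s}" for i, s in enumerate(self.level_sizes)
            ]
        for i, (m, r) in enumerate(zip(b["filters"], self.ratios), start=1):
            lines.append(f"  B{i}: m = {m} bits (r = {r:.3f})")
        lines.append(f"  T{self.t} table: {b['residual']} bits ({len(self.residual)} k-mers)")
        lines.append(f"  total: {b['total']} bits = {b['bits_per_kmer']:.3f} bits/k-mer")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------
    # magic "CDBG", u8 version, u8 k, u8 t, u64 N, u64 master seed,
    # t*f64 ratios, then per filter a BLMF block + u32 crc32, then
    # u64 |T_t|, packed sorted codes (ceil(2k/8) bytes each) + u32 crc32.

    def save(self, path) -> None:
        nb = (2 * self.k + 7) // 8
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<BBBQQ", _VERSION, self.k, self.t, self.n_true,
                                 self.master_seed & (2**64 - 1)))
            fh.write(struct.pack(f"<{self.t}d", *self.ratios))
            for f in self.filters:
                blob = f.to_bytes()
                fh.write(struct.pack("<Q", len(blob)))
                fh.write(blob)
                fh.write(struct.pack("<I", zlib.crc32(blob)))
            resid = b"".join(int(c).to_bytes(nb, "little") for c in self.residual)
            fh.write(struct.pack("<Q", len(self.residual)))
            fh.write(resid)
            fh.write(struct.pack("<I", zlib.crc32(resid)))

    @classmethod
    def load(cls, path) -> "CascadingDBG":
        def need(fh, n, what):
            blob = fh.read(n)
            if len(blob) != n:
                raise ValueError(f"truncated structure file ({what})")
            return blob

        with open(path, "rb") as fh:
            if need(fh, 4, "magic") != _MAGIC:
                raise ValueError("not a cascade structure file (bad magic)")
            version, k, t, n_true, seed = struct.unpack("<BBBQQ", need(fh, 19, "header"))
            if version != _VERSION:
                raise ValueError(f"unsupported structure version {version}")
            ratios = struct.unpack(f"<{t}d", need(fh, 8 * t, "ratios"))
            filters = []
            for i in range(t):
                (ln,) = struct.unpack("<Q", need(fh, 8, f"B{i+1} length"))
                blob = need(fh, ln, f"B{i+1} block")
                (crc,) = struct.unpack("<I", need(fh, 4, f"B{i+1} checksum"))
                if zlib.crc32(blob) != crc:
                    raise ValueError(f"checksum mismatch in filter B{i+1}")
                filters.append(BloomFilter.from_bytes(blob))
            (nres,) = struct.unpack("<Q", need(fh, 8, "residual length"))
            nb = (2 * k + 7) // 8
            resid = need(fh, nres * nb, "residual codes")
            (crc,) = struct.unpack("<I", need(fh, 4, "residual checksum"))
            if zlib.crc32(resid) != crc:
                raise ValueError("checksum mismatch in residual table")
        if k <= 31:
            codes = np.frombuffer(resid, dtype=np.uint8).reshape(nres, nb) if nres else None
            if nres:
                vals = np.zeros(nres, dtype=np.uint64)
                for j in range(nb):
                    vals |= codes[:, j].astype(np.uint64) << np.uint64(8 * j)
                residual = vals
            else:
                residual = np.empty(0, dtype=np.uint64)
        else:
            residual = np.array(
                [int.from_bytes(resid[i * nb : (i + 1) * nb], "little") for i in range(nres)],
                dtype=object,
            )
        return cls(k, filters, residual, ratios, n_true, master_seed=seed)


def _empty_like(t0_codes: np.ndarray) -> np.ndarray:
    if t0_codes.dtype == object:
        return np.empty(0, dtype=object)
    return np.empty(0, dtype=np.uint64)


def _setdiff_sorted(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for strictly sorted arrays."""
    if len(a) == 0 or len(b) == 0:
        return a
    idx = np.minimum(np.searchsorted(b, a), len(b) - 1)
    return a[b[idx] != a]


def _critical_false_positives(
    t0_codes: np.ndarray, k: int, b1: BloomFilter, partitions: Optional[int]
) -> np.ndarray:
    """T1: potential neighbors of T0 present in B1 but not in T0.

    All 8 extensions of every T0 member are queried against B1; the
    survivors are deduplicated and T0 members removed. With
    ``partitions`` set, candidate generation and the set difference run
    in chunks (spilling survivors to scratch files), mirroring the
    partitioned on-disk construction used at genome scale.
    """
    if partitions and partitions > 1:
        import tempfile

        nchunk = max(1, -(-len(t0_codes) // partitions))
        paths = []
        with tempfile.TemporaryDirectory(prefix="cascade_t1_") as tmp:
            for ci in range(0, len(t0_codes), nchunk):
                cand = neighbor_matrix(t0_codes[ci : ci + nchunk], k).ravel()
                cand = np.unique(cand)
                surv = cand[b1.contains_many(cand)]
                p = Path(tmp) / f"part{ci}.npy"
                np.save(p, surv, allow_pickle=surv.dtype == object)
                paths.append(p)
            parts = [np.load(p, allow_pickle=True) for p in paths]
        cand = np.unique(np.concatenate(parts)) if parts else _empty_like(t0_codes)
    else:
        cand = np.unique(neighbor_matrix(t0_codes, k).ravel())
        cand = cand[b1.contains_many(cand)]
    return _setdiff_sorted(cand, t0_codes)


def build(
    t0: KmerSet,
    t: int = 4,
    ratios: Union[float, Sequence[float], None] = None,
    master_seed: int = DEFAULT_SEED,
    partitions: Optional[int] = None,
) -> CascadingDBG:
    """Construct the cascade ``B1..Bt`` + ``T_t`` from the node set ``T0``.

    ``ratios`` may be a single bits-per-element value (replicated), an
    explicit vector ``r1..rt``, or ``None`` to use the memory-optimal
    single ratio for the chosen ``(k, t)``. Construction is off-line:
    ``B1`` holds ``T0``; ``T1`` is the critical-false-positive set; for
    ``i >= 2``, ``B_i`` (sized ``r_i * |T_{i-1}|``) holds ``T_{i-1}``
    and ``T_i`` collects members of ``T_{i-2}`` that ``B_i`` wrongly
    reports. An empty ``T_{i-1}`` yields the degenerate 1-bit filter and
    all later levels empty.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(t0) == 0:
        raise ValueError("T0 must be nonempty")
    if ratios is None:
        r_opt, _ = estimator.optimize_r(t, t0.k)
        rvec = [r_opt] * t
    elif np.isscalar(ratios):
        rvec = [float(ratios)] * t
    else:
        rvec = [float(r) for r in ratios]
        if len(rvec) != t:
            raise ValueError(f"expected {t} ratios, got {len(rvec)}")
    if any(r <= 0 for r in rvec):
        raise ValueError("ratios must be positive")

    codes0 = t0.codes
    n = len(codes0)
    b1 = make_filter(n, rvec[0], seed=derive_seed(master_seed, 1))
    b1.insert_many(codes0)
    filters = [b1]
    t1 = _critical_false_positives(codes0, t0.k, b1, partitions)
    level_sizes = [n, len(t1)]
    prev2, prev1 = codes0, t1
    for i in range(2, t + 1):
        bi = make_filter(len(prev1), rvec[i - 1], seed=derive_seed(master_seed, i))
        bi.insert_many(prev1)
        filters.append(bi)
        ti = prev2[bi.contains_many(prev2)] if len(prev1) else _empty_like(codes0)
        level_sizes.append(len(ti))
        prev2, prev1 = prev1, ti
    residual = prev1  # == T_t, sorted (subset of a sorted array)
    return CascadingDBG(
        t0.k, filters, residual, rvec, n, level_sizes, master_seed=master_seed
    )
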