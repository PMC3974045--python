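"""K-mer encoding, canonicalization, neighbor enumeration and counting.

A k-mer is a DNA word of length ``k`` over {A, C, G, T}, packed two bits
per base with the leftmost base in the most significant pair, so that
integer order on codes equals lexicographic order on strings (A < C < G
< T). Every stored k-mer is *canonical*: the smaller of the word and its
reverse complement, which folds the two strands of a genome onto one
representative.

In the de Bruijn graph sense used in assembly, the nodes are the
distinct canonical k-mers of a read set and arcs join k-mers overlapping
by k-1 letters; a node therefore has at most 2*4 = 8 *potential
neighbors* (4 right extensions, 4 left extensions), which is the only
query pattern a graph traversal ever issues.

k up to 31 runs on vectorized uint64 arrays; 32 <= k <= 64 uses an
equivalent scalar path on Python ints (codes held in object arrays).
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from ._bits import (
    canonical_code,
    canonical_codes_u64,
    revcomp_code,
)

__all__ = [
    "Kmer",
    "KmerSet",
    "encode",
    "decode",
    "potential_neighbors",
    "count_kmers",
    "read_sequences",
]

BASES = "ACGT"
MAX_K = 64
_FAST_K = 31  # codes fit a uint64

# byte -> 2-bit base value, 255 for anything not ACGTacgt
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True, order=True)
class Kmer:
    """A canonical k-mer: packed 2-bit code plus its length."""

    code: int
    k: int

    def __post_init__(self):
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if not 0 <= self.code < 4**self.k:
            raise ValueError("code out of range for k")

    def __str__(self) -> str:
        return decode(self.code, self.k)

    @property
    def is_canonical(self) -> bool:
        return self.code <= revcomp_code(self.code, self.k)

    def reverse_complement(self) -> "Kmer":
        return Kmer(revcomp_code(self.code, self.k), self.k)


def encode(sequence: str) -> Kmer:
    """Pack a DNA string into its canonical :class:`Kmer`.

    Raises ``ValueError`` naming the offending position for any
    character outside ACGT (case-insensitive); callers scanning reads
    skip windows spanning such characters rather than altering them.
    """
    k = len(sequence)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    code = 0
    for pos, ch in enumerate(sequence):
        v = _BASE_LUT[ord(ch) & 0xFF] if ord(ch) < 256 else 255
        if v == 255:
            raise ValueError(f"non-ACGT character {ch!r} at position {pos}")
        code = (code << 2) | int(v)
    return Kmer(canonical_code(code, k), k)


def decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def potential_neighbors(u: Kmer) -> list[Kmer]:
    """The <= 8 canonical k-mers overlapping ``u`` by k-1 letters.

    Order is deterministic: right extensions with A, C, G, T then left
    extensions with A, C, G, T, deduplicated keeping first occurrence
    (palindromic and self-overlapping cases can collide).
    """
    k = u.k
    mask = (1 << (2 * k)) - 1
    out: list[Kmer] = []
    seen: set[int] = set()
    for b in range(4):  # right: suffix(k-1) + base
        c = canonical_code(((u.code << 2) & mask) | b, k)
        if c not in seen:
            seen.add(c)
            out.append(Kmer(c, k))
    for b in range(4):  # left: base + prefix(k-1)
        c = canonical_code((b << (2 * (k - 1))) | (u.code >> 2), k)
        if c not in seen:
            seen.add(c)
            out.append(Kmer(c, k))
    return out


# ---------------------------------------------------------------------------
# bulk code helpers (shared with cascade/traversal)


def canonicalize_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical form of an array of packed codes (either dtype path)."""
    codes = np.asarray(codes)
    if codes.dtype == object:
        return np.array([canonical_code(int(c), k) for c in codes], dtype=object)
    return canonical_codes_u64(codes.astype(np.uint64), k)


def neighbor_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """(n, 8) canonical codes of all potential neighbors, per node.

    Columns 0-3 are right extensions A, C, G, T; columns 4-7 left
    extensions A, C, G, T. Duplicates are *not* removed: this is the
    exact 8-query-per-node multiset a graph traversal issues.
    """
    codes = np.asarray(codes)
    if codes.dtype == object:
        rows = []
        mask = (1 << (2 * k)) - 1
        for c in codes:
            c = int(c)
            row = [canonical_code(((c << 2) & mask) | b, k) for b in range(4)]
            row += [
                canonical_code((b << (2 * (k - 1))) | (c >> 2), k) for b in range(4)
            ]
            rows.append(row)
        return np.array(rows, dtype=object)
    u = np.uint64
    codes = codes.astype(np.uint64)
    mask = u((1 << (2 * k)) - 1)
    out = np.empty((len(codes), 8), dtype=np.uint64)
    for b in range(4):
        out[:, b] = canonical_codes_u64(((codes << u(2)) & mask) | u(b), k)
        out[:, 4 + b] = canonical_codes_u64(
            (u(b) << u(2 * (k - 1))) | (codes >> u(2)), k
        )
    return out


def _codes_of_read(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every valid k-window of one read (k <= 31)."""
    vals = _BASE_LUT[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = np.concatenate(([0], np.cumsum(vals == 255)))
    valid = (bad[k:] - bad[:-k]) == 0
    codes = np.zeros(n, dtype=np.uint64)
    v64 = vals.astype(np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | v64[j : j + n]
    codes = codes[valid]
    return canonical_codes_u64(codes, k)


def _codes_of_read_wide(seq: str, k: int) -> list[int]:
    out = []
    code = 0
    run = 0  # valid bases accumulated
    mask = (1 << (2 * k)) - 1
    for ch in seq:
        v = _BASE_LUT[ord(ch) & 0xFF] if ord(ch) < 256 else 255
        if v == 255:
            run = 0
            code = 0
            continue
        code = ((code << 2) | int(v)) & mask
        run += 1
        if run >= k:
            out.append(canonical_code(code, k))
    return out


class KmerSet:
    """Deduplicated set of canonical k-mer codes, optionally with counts.

    ``codes`` is kept strictly sorted (uint64 array for k <= 31, object
    array of Python ints otherwise), so membership is a binary search
    and set algebra reduces to ``searchsorted``.
    """

    def __init__(self, k: int, codes: np.ndarray, counts: Optional[np.ndarray] = None):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}]")
        self.k = int(k)
        self.codes = np.asarray(codes)
        self.counts = None if counts is None else np.asarray(counts, dtype=np.uint32)
        if len(self.codes) > 1 and not all(
            self.codes[i] < self.codes[i + 1] for i in range(min(len(self.codes) - 1, 2))
        ):
            # cheap guard; full sortedness is the constructor's contract
            raise ValueError("codes must be strictly sorted")

    @classmethod
    def from_codes(
        cls, k: int, codes: Iterable[int], counts: Optional[Iterable[int]] = None
    ) -> "KmerSet":
        """Build from possibly unsorted, possibly duplicated canonical codes."""
        if k <= _FAST_K:
            arr = np.fromiter((int(c) for c in codes), dtype=np.uint64)
        else:
            arr = np.array([int(c) for c in codes], dtype=object)
        if counts is not None:
            cnt = np.asarray(list(counts), dtype=np.uint32)
            order = np.argsort(arr, kind="stable")
            return cls(k, arr[order], cnt[order])
        uniq = np.unique(arr)
        return cls(k, uniq)

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[Kmer]:
        for c in self.codes:
            yield Kmer(int(c), self.k)

    def contains(self, code: int) -> bool:
        i = np.searchsorted(self.codes, code)
        return i < len(self.codes) and int(self.codes[i]) == int(code)

    def contains_many(self, codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.codes, codes)
        idx = np.minimum(idx, len(self.codes) - 1) if len(self.codes) else idx
        if len(self.codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        return self.codes[idx] == codes

    def __contains__(self, item) -> bool:
        if isinstance(item, Kmer):
            if item.k != self.k:
                return False
            return self.contains(item.code)
        return self.contains(int(item))

    # -- text / binary formats --------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.counts is None:
                for c in self.codes:
                    fh.write(f"{decode(int(c), self.k)}\t1\n")
            else:
                for c, n in zip(self.codes, self.counts):
                    fh.write(f"{decode(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerSet":
        codes, counts, k = [], [], None
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                word, _, cnt = line.rstrip("\n").partition("\t")
                if k is None:
                    k = len(word)
                elif len(word) != k:
                    raise ValueError("mixed k-mer lengths in TSV")
                codes.append(encode(word).code)
                counts.append(int(cnt) if cnt else 1)
        if k is None:
            raise ValueError("empty k-mer TSV")
        ks = cls.from_codes(k, codes, counts)
        return ks

    # packed binary: magic "KMRS", u8 k, u64 n, then n records of
    # ceil(2k/8) code bytes (little-endian) + u32 count.

    _MAGIC = b"KMRS"

    def to_binary(self, path) -> None:
        nb = (2 * self.k + 7) // 8
        with open(path, "wb") as fh:
            fh.write(self._MAGIC + struct.pack("<BQ", self.k, len(self.codes)))
            counts = (
                self.counts
                if self.counts is not None
                else np.ones(len(self.codes), dtype=np.uint32)
            )
            for c, n in zip(self.codes, counts):
                fh.write(int(c).to_bytes(nb, "little") + struct.pack("<I", int(n)))

    @classmethod
    def from_binary(cls, path) -> "KmerSet":
        with open(path, "rb") as fh:
            head = fh.read(13)
            if head[:4] != cls._MAGIC:
                raise ValueError("not a k-mer set file (bad magic)")
            k, n = struct.unpack("<BQ", head[4:])
            nb = (2 * k + 7) // 8
            rec = nb + 4
            blob = fh.read(n * rec)
            if len(blob) != n * rec:
                raise ValueError("truncated k-mer set file")
        codes, counts = [], []
        for i in range(n):
            off = i * rec
            codes.append(int.from_bytes(blob[off : off + nb], "little"))
            counts.append(struct.unpack_from("<I", blob, off + nb)[0])
        return cls.from_codes(k, codes, counts)


def count_kmers(reads: Sequence[str], k: int, d: int = 0) -> KmerSet:
    """Canonical k-mers occurring *more than* ``d`` times across reads.

    Both orientations of every window fold onto the canonical code
    before counting; windows containing non-ACGT characters are skipped;
    reads shorter than k contribute nothing. The retained set is
    {u : count(u) >= d + 1} (equivalently an inclusive min-count of
    d + 1), the abundance cutoff used to drop sequencing-error k-mers.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    if d < 0:
        raise ValueError("d must be >= 0")
    if k <= _FAST_K:
        chunks = [_codes_of_read(r, k) for r in reads]
        allc = (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
        )
        if len(allc) == 0:
            return KmerSet(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint32))
        uniq, cnt = np.unique(allc, return_counts=True)
        keep = cnt >= d + 1
        return KmerSet(k, uniq[keep], cnt[keep].astype(np.uint32))
    tally: dict[int, int] = {}
    for r in reads:
        for c in _codes_of_read_wide(r, k):
            tally[c] = tally.get(c, 0) + 1
    items = sorted((c, n) for c, n in tally.items() if n >= d + 1)
    codes = np.array([c for c, _ in items], dtype=object)
    counts = np.array([n for _, n in items], dtype=np.uint32)
    return KmerSet(k, codes, counts)


# ---------------------------------------------------------------------------
# sequence file reading (FASTA/FASTQ, plain or gzipped)


def read_sequences(path) -> list[str]:
    """Sequences from a FASTA/FASTQ file (``.gz`` transparent); qualities ignored."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith((".fq", ".fastq")):
        fmt = "fastq"
    elif stem.endswith((".fa", ".fasta", ".fna")):
        fmt = "fasta"
    else:
        raise ValueError(f"cannot infer sequence format from {path.name!r}")
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
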