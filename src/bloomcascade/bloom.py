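"""Classic Bloom filter over packed k-mer codes.

A filter is a bitmap of ``m`` bits probed by ``p`` hash functions; an
element is present when all ``p`` probed bits are set, giving one-sided
error (false positives, never false negatives). With ``r = m/n`` bits
per stored element the false positive rate is

    F = (1 - exp(-p/r))**p,

minimized at ``p = r*ln 2`` where ``F ~ 0.6185**r``.

The ``p`` probe positions come from double hashing, ``h_i = a + i*b mod
m``, with ``a`` and ``b`` two independently seeded 64-bit hashes of the
packed code; this behaves as independent uniform positions at the
tolerances relevant here, and keeps the whole structure reproducible
from a single master seed.
"""

from __future__ import annotations

import struct
import zlib
from math import exp, log

import numpy as np

from ._bits import MASK64, derive_seed, hash_code, hash_codes_arr

__all__ = ["BloomFilter", "make_filter", "fp_rate", "DEFAULT_SEED"]

DEFAULT_SEED = 0x5EED_CA5CADE

_U = np.uint64
_MAGIC = b"BLMF"


def fp_rate(r: float, p: int) -> float:
    """False positive probability (1 - e^(-p/r))^p for load r = m/n."""
    if r <= 0:
        raise ValueError("r must be positive")
    if p < 1:
        raise ValueError("p must be >= 1")
    return (1.0 - exp(-p / r)) ** p


class BloomFilter:
    """Bitmap of ``m`` bits with ``p`` seeded hash functions."""

    __slots__ = ("m", "p", "seed", "_words", "_seed_a", "_seed_b", "n_inserted")

    def __init__(self, m: int, p: int, seed: int = DEFAULT_SEED):
        if m < 1 or p < 1:
            raise ValueError("need m >= 1 and p >= 1")
        self.m = int(m)
        self.p = int(p)
        self.seed = int(seed) & MASK64
        self._seed_a = derive_seed(self.seed, 1)
        self._seed_b = derive_seed(self.seed, 2)
        self._words = np.zeros((self.m + 63) // 64, dtype=np.uint64)
        self.n_inserted = 0

    # -- scalar path (any code width) -------------------------------------

    def _positions(self, code: int):
        a = hash_code(code, self._seed_a)
        b = hash_code(code, self._seed_b) | 1
        return [((a + i * b) & MASK64) % self.m for i in range(self.p)]

    def insert(self, code: int) -> None:
        w = self._words
        for pos in self._positions(code):
            w[pos >> 6] |= _U(1) << _U(pos & 63)
        self.n_inserted += 1

    def contains(self, code: int) -> bool:
        w = self._words
        for pos in self._positions(code):
            if not (int(w[pos >> 6]) >> (pos & 63)) & 1:
                return False
        return True

    # -- vectorized path (uint64 codes, k <= 31) ---------------------------

    def _positions_arr(self, codes: np.ndarray):
        a = hash_codes_arr(codes, self._seed_a)
        b = hash_codes_arr(codes, self._seed_b) | _U(1)
        m = _U(self.m)
        for i in range(self.p):
            yield (a + _U(i) * b) % m

    def insert_many(self, codes: np.ndarray) -> None:
        codes = np.asarray(codes)
        if codes.dtype == object:
            for c in codes:
                self.insert(int(c))
            return
        w = self._words
        for pos in self._positions_arr(codes):
            np.bitwise_or.at(w, pos >> _U(6), _U(1) << (pos & _U(63)))
        self.n_inserted += len(codes)

    def contains_many(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes)
        if codes.dtype == object:
            return np.array([self.contains(int(c)) for c in codes], dtype=bool)
        w = self._words
        out = np.ones(len(codes), dtype=bool)
        for pos in self._positions_arr(codes):
            out &= ((w[pos >> _U(6)] >> (pos & _U(63))) & _U(1)).astype(bool)
        return out

    # -- misc ---------------------------------------------------------------

    @property
    def bits_set(self) -> int:
        return int(np.unpackbits(self._words.view(np.uint8)).sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BloomFilter)
            and self.m == other.m
            and self.p == other.p
            and self.seed == other.seed
            and np.array_equal(self._words, other._words)
        )

    def __repr__(self) -> str:
        return f"BloomFilter(m={self.m}, p={self.p}, seed={self.seed:#x})"

    # -- serialization ------------------------------------------------------
    # layout: magic "BLMF", u64 m, u8 p, u64 seed, ceil(m/8) bitmap bytes
    # (bit j of the map lives in byte j>>3, bit j&7).

    def to_bytes(self) -> bytes:
        nbytes = (self.m + 7) // 8
        bitmap = self._words.view(np.uint8).tobytes()[:nbytes]
        return _MAGIC + struct.pack("<QBQ", self.m, self.p, self.seed) + bitmap

    @classmethod
    def from_bytes(cls, blob: bytes) -> "BloomFilter":
        if blob[:4] != _MAGIC:
            raise ValueError("not a Bloom filter block (bad magic)")
        m, p, seed = struct.unpack_from("<QBQ", blob, 4)
        nbytes = (m + 7) // 8
        bitmap = blob[21 : 21 + nbytes]
        if len(bitmap) != nbytes:
            raise ValueError("truncated Bloom filter block")
        f = cls(m, p, seed)
        raw = np.zeros(len(f._words) * 8, dtype=np.uint8)
        raw[:nbytes] = np.frombuffer(bitmap, dtype=np.uint8)
        f._words = raw.view(np.uint64).copy()
        return f

    def byte_size(self) -> int:
        return 21 + (self.m + 7) // 8

    def checksum(self) -> int:
        return zlib.crc32(self.to_bytes())


def make_filter(n_expected: int, r: float, seed: int = DEFAULT_SEED) -> BloomFilter:
    """Size a filter for ``n_expected`` elements at ``r`` bits per element.

    ``m = max(1, round(r*n))`` and ``p = max(1, round(r*ln 2))``, the
    integer rounding of the optimal hash count. ``n_expected = 0`` gives
    the degenerate 1-bit filter that answers *no* until an insert.
    """
    if n_expected < 0:
        raise ValueError("n_expected must be >= 0")
    if r <= 0:
        raise ValueError("r must be positive")
    m = max(1, round(r * n_expected))
    p = max(1, round(r * log(2)))
    return BloomFilter(m, p, seed)
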