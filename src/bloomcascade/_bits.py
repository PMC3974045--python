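"""Low-level 2-bit k-mer code manipulation and deterministic hashing.

K-mers are packed two bits per base (A=00, C=01, G=10, T=11), most
significant pair first, so integer comparison of codes equals
lexicographic comparison of the strings. Codes for k <= 31 fit a single
uint64 and take vectorized numpy paths; wider k-mers (up to k = 64, 128
bits) use equivalent scalar arithmetic on Python ints.

Hashing is a splitmix64-style finalizer; Bloom filters combine two
seeded hashes by double hashing. Everything here is deterministic given
the seed.
"""

from __future__ import annotations

import numpy as np

MASK64 = (1 << 64) - 1

_M1 = 0xBF58476D1CE4E5B9
_M2 = 0x94D049BB133111EB
_SEED_GAMMA = 0x9E3779B97F4A7C15

# numpy uint64 constants (avoid repeated casting in hot loops)
_U = np.uint64
_N_M1 = _U(_M1)
_N_M2 = _U(_M2)


def mix64(z: int) -> int:
    """splitmix64 finalizer on a Python int (64-bit wrap-around)."""
    z &= MASK64
    z ^= z >> 30
    z = (z * _M1) & MASK64
    z ^= z >> 27
    z = (z * _M2) & MASK64
    z ^= z >> 31
    return z


def mix64_arr(z: np.ndarray) -> np.ndarray:
    z = z.astype(np.uint64, copy=True)
    z ^= z >> _U(30)
    z *= _N_M1
    z ^= z >> _U(27)
    z *= _N_M2
    z ^= z >> _U(31)
    return z


def hash_code(code: int, seed: int) -> int:
    """Hash an arbitrary-width packed code (<=128 bits) to 64 bits."""
    lo = code & MASK64
    hi = code >> 64
    h = mix64(lo ^ seed)
    if hi:
        h = mix64(h ^ mix64(hi ^ seed))
    return h


def hash_codes_arr(codes: np.ndarray, seed: int) -> np.ndarray:
    """Vectorized counterpart of :func:`hash_code` for uint64 codes."""
    return mix64_arr(codes ^ _U(seed & MASK64))


def derive_seed(master: int, index: int) -> int:
    """Deterministic stream of sub-seeds from one master seed."""
    return mix64(master + index * _SEED_GAMMA)


# ---------------------------------------------------------------------------
# reverse complement on packed codes

_C2 = 0x3333333333333333
_C4 = 0x0F0F0F0F0F0F0F0F


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed code, any k <= 64."""
    r = 0
    for _ in range(k):
        r = (r << 2) | (3 - (code & 3))
        code >>= 2
    return r


def revcomp_codes_u64(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement for k <= 31 (codes in uint64)."""
    x = (~codes).astype(np.uint64)
    x = ((x >> _U(2)) & _U(_C2)) | ((x & _U(_C2)) << _U(2))
    x = ((x >> _U(4)) & _U(_C4)) | ((x & _U(_C4)) << _U(4))
    x = x.byteswap()
    return x >> _U(64 - 2 * k)


def canonical_code(code: int, k: int) -> int:
    rc = revcomp_code(code, k)
    return code if code <= rc else rc


def canonical_codes_u64(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(codes, revcomp_codes_u64(codes, k))
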