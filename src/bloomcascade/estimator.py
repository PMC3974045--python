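"""Closed-form memory and query-distribution models for the cascade.

All expressions are per stored k-mer and use ``c = 0.6185``, the base of
the optimal Bloom filter false-positive rate ``F ~ c**r`` at ``p = r*ln
2`` hash functions (``c`` is kept at this printed value rather than
recomputed as ``(1/2)**ln 2`` so the model tables are bit-stable).

Memory model. With ``N = |T0|`` nodes and a single ratio ``r``, the
bitmap sizes follow the series ``rN, 6rNc^r, rNc^r, 6rNc^2r, rNc^2r,
…``: each node has 8 potential neighbors of which ~2 are real, so ~6
extensions per node can become critical false positives (the ``6c^r``
terms), while the even-level "false false positive" sets are fractions
of ``T0`` itself (the ``c^r`` terms). Summed to infinity the bits per
k-mer are ``(1 + 6c^r) * r / (1 - c^r)``, minimized at ``r = 5.464``
(8.45 bits). Truncating at ``t`` filters adds an explicit residual
table of ``2k`` bits per stored k-mer: ``2k * c^(ceil(t/2)*r)`` for even
``t`` or ``2k * 6 * c^(ceil(t/2)*r)`` for odd ``t``.

Per-filter ratios generalize the series by accumulating exponents along
the odd chain (filters 1, 3, 5, … guard ``T0``-derived sets) and the
even chain (filters 2, 4, … guard ``T1``-derived sets):
``r1 + 6 r2 c^{r1} + r3 c^{r2} + 6 r4 c^{r1+r3} + r5 c^{r2+r4} + …``.

Query model. An exhaustive traversal visiting each of the ``N`` true
nodes once issues all 8 potential-neighbor queries per node, 8N total,
~2N of which hit true neighbors. The fraction resolved (answered *no*)
by successive filters alternates ``(6 - 6c^r)/8, (2 - 2c^r)/8,
(6c^r - 6c^2r)/8, (2c^r - 2c^2r)/8, …``; whatever remains reaches the
residual table.

The single-filter baseline (no cascade) uses the original 8-extension
estimate: ``r1 = 1.44*log2(16k/2.08)`` and ``1.44*log2(16k/2.08) +
2.08`` bits per k-mer, so doubling ``k`` costs exactly 1.44 bits.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

__all__ = [
    "C",
    "bits_per_kmer_infinite",
    "bits_per_kmer_truncated",
    "bits_per_kmer_vector",
    "bits_per_kmer_vector_infinite",
    "optimize_r",
    "optimize_r_infinite",
    "optimize_vector",
    "optimize_vector_infinite",
    "baseline_r1",
    "baseline_t1",
    "query_distribution",
    "QueryDistribution",
    "table1",
    "table2",
    "table3",
    "table4",
    "render_tables",
]

C = 0.6185

# The F ~ c**r model presumes the optimal hash count p = r*ln2 is at
# least 1, so ratios below 1/ln2 are outside the model's validity; all
# optimizations respect this bound (the tied per-filter optimum sits
# exactly on it).
R_MIN = 1.0 / math.log(2.0)
_R_BOUNDS = (R_MIN, 30.0)
_XATOL = 1e-9  # well under the 1e-6 reproducibility tolerance


def bits_per_kmer_infinite(r: float) -> float:
    """Bits per k-mer of the un-truncated cascade, (1 + 6c^r) r / (1 - c^r)."""
    if r <= 0:
        raise ValueError("r must be positive")
    cr = C**r
    return (1.0 + 6.0 * cr) * r / (1.0 - cr)


def _bitmap_series(r: float, t: int) -> float:
    """Sum of the first t bitmap terms: r, 6rc^r, rc^r, 6rc^2r, rc^2r, …"""
    total = r
    for i in range(2, t + 1):
        j = i // 2  # exponent multiplier
        coef = 6.0 if i % 2 == 0 else 1.0
        total += coef * r * C ** (j * r)
    return total


def bits_per_kmer_truncated(r: float, t: int, k: int) -> float:
    """Bits per k-mer with t filters plus the explicit 2k-bit residual table.

    The residual holds ``N c^(ceil(t/2) r)`` k-mers for even ``t`` (a
    subset of T0) or six times that for odd ``t`` (a subset of T1).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if t < 1:
        raise ValueError("t must be >= 1")
    half = -(-t // 2)  # ceil(t/2)
    coef = 1.0 if t % 2 == 0 else 6.0
    return _bitmap_series(r, t) + 2.0 * k * coef * C ** (half * r)


def baseline_r1(k: int) -> float:
    """Filter ratio of the single-filter baseline, 1.44 log2(16k/2.08)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.44 * math.log2(16 * k / 2.08)


def baseline_t1(k: int) -> float:
    """Bits per k-mer of the single-filter baseline, r1 + 2.08."""
    return baseline_r1(k) + 2.08


def optimize_r_infinite() -> tuple[float, float]:
    """(r, bits) minimizing the un-truncated model; ~ (5.464, 8.45)."""
    res = optimize.minimize_scalar(
        bits_per_kmer_infinite, bounds=_R_BOUNDS, method="bounded",
        options={"xatol": _XATOL},
    )
    return float(res.x), float(res.fun)


def optimize_r(t: int, k: int) -> tuple[float, float]:
    """(r, bits) minimizing the truncated model for given t and k.

    ``t = 1`` returns the baseline convention (8-extension estimate)
    rather than minimizing the 6-extension truncated sum, matching the
    original single-filter method this structure is compared against.
    """
    if t == 1:
        return baseline_r1(k), baseline_t1(k)
    res = optimize.minimize_scalar(
        lambda r: bits_per_kmer_truncated(r, t, k),
        bounds=_R_BOUNDS, method="bounded", options={"xatol": _XATOL},
    )
    return float(res.x), float(res.fun)


# ---------------------------------------------------------------------------
# per-filter ratios


def bits_per_kmer_vector(ratios: Sequence[float], k: int) -> float:
    """Bits per k-mer with per-filter ratios r1..rt and a 2k-bit residual.

    Terms: ``r1 + 6 r2 c^{r1} + r3 c^{r2} + 6 r4 c^{r1+r3} + …``; the
    residual multiplies ``2k`` (even ``t``) or ``2k*6`` (odd ``t``) by
    ``c`` raised to the completed chain sum. Equal ratios reduce exactly
    to :func:`bits_per_kmer_truncated`.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("need at least one ratio")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    t = len(ratios)
    total = 0.0
    odd_acc = even_acc = 0.0
    for i, r in enumerate(ratios, start=1):
        if i % 2 == 1:
            coef, exp = 1.0, even_acc
            odd_acc += r
        else:
            coef, exp = 6.0, odd_acc
            even_acc += r
        total += coef * r * C**exp
    if t % 2 == 0:
        total += 2.0 * k * C**even_acc
    else:
        total += 2.0 * k * 6.0 * C**odd_acc
    return total


def bits_per_kmer_vector_infinite(r1: float, r_rest: float) -> float:
    """Un-truncated per-filter model with ratios tied beyond the first.

    With ``x = r1`` and all later ratios ``y``, the chains are geometric
    and the series closes to ``x + (6 y c^x + y c^y) / (1 - c^y)``.
    """
    if r1 <= 0 or r_rest <= 0:
        raise ValueError("ratios must be positive")
    cy = C**r_rest
    return r1 + (6.0 * r_rest * C**r1 + r_rest * cy) / (1.0 - cy)


def optimize_vector_infinite() -> tuple[float, float, float]:
    """(r1, r_rest, bits) minimizing the tied infinite model; ~7.93 bits."""
    res = optimize.minimize(
        lambda v: bits_per_kmer_vector_infinite(v[0], v[1]),
        x0=np.array([5.0, 2.0]),
        bounds=[_R_BOUNDS, _R_BOUNDS],
        method="L-BFGS-B",
    )
    return float(res.x[0]), float(res.x[1]), float(res.fun)


def optimize_vector(t: int, k: int) -> tuple[list[float], float]:
    """(r1..rt, bits) minimizing the per-filter truncated model.

    Deterministic multi-start local optimization from a fixed coarse
    grid of starting vectors; the objective is near-flat around its
    minimum, so the minimized *bits* value is the reproducible quantity,
    not the exact argmin vector.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    r_single, _ = optimize_r(t, k) if t > 1 else (baseline_r1(k), 0.0)
    starts = [np.full(t, r_single)]
    for lo, hi in ((3.0, 6.0), (2.0, 9.0), (5.0, 10.0)):
        v = np.full(t, lo)
        v[0] = (lo + hi) / 2
        if t >= 4:
            v[3::2] = hi  # deeper even filters favor larger ratios
        starts.append(v)
    starts.append(np.linspace(4.0, 9.0, t))
    best_x, best_f = None, math.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda v: bits_per_kmer_vector(v, k),
            x0=x0,
            bounds=[_R_BOUNDS] * t,
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    return [float(v) for v in best_x], best_f


# ---------------------------------------------------------------------------
# query distribution


@dataclass
class QueryDistribution:
    """Fractions of the 8N traversal queries resolved per level.

    ``levels[i]`` is the fraction answered *no* by filter ``B_{i+1}``;
    ``residual`` is the fraction that reaches the explicit ``T_t``
    table (0 for the un-truncated model). Fractions sum to 1.
    """

    levels: list[float]
    residual: float

    @property
    def fractions(self) -> list[float]:
        return self.levels + [self.residual]

    def cumulative(self, n: int) -> float:
        """Fraction resolved by the first n filters."""
        return sum(self.levels[:n])


def query_distribution(
    ratios: Union[float, Sequence[float], None] = None,
    t: Union[int, float] = 4,
    k: Optional[int] = None,
) -> QueryDistribution:
    """Model the per-level resolution of the 8-queries-per-node traversal.

    ``t`` may be ``math.inf`` for the un-truncated cascade (levels are
    emitted until their mass is negligible). ``ratios`` defaults to the
    memory-optimal ratio for ``(t, k)``; a scalar is replicated; a
    vector generalizes the powers of ``c^r`` to accumulated chain
    products. Per level the resolved fractions alternate between the
    six "extension" queries and the two "true neighbor" queries:
    ``(6 - 6c^r)/8, (2 - 2c^r)/8, (6c^r - 6c^2r)/8, …``.
    """
    infinite = math.isinf(t)
    if ratios is None:
        if k is None:
            raise ValueError("need k to resolve the optimal ratio")
        if infinite:
            r, _ = optimize_r_infinite()
        else:
            r, _ = optimize_r(int(t), k)
        rs: Optional[list[float]] = None if infinite else [r] * int(t)
        r_scalar = r
    elif np.isscalar(ratios):
        r_scalar = float(ratios)
        rs = None if infinite else [r_scalar] * int(t)
    else:
        if infinite:
            raise ValueError("an infinite cascade needs a scalar ratio")
        rs = [float(x) for x in ratios]
        if len(rs) != int(t):
            raise ValueError(f"expected {t} ratios, got {len(rs)}")
        r_scalar = rs[0]

    levels: list[float] = []
    odd_prod = even_prod = 1.0  # c^(sum of resolved chain ratios)
    if infinite:
        i = 1
        while True:
            if i % 2 == 1:
                new = odd_prod * C**r_scalar
                levels.append(6.0 * (odd_prod - new) / 8.0)
                odd_prod = new
            else:
                new = even_prod * C**r_scalar
                levels.append(2.0 * (even_prod - new) / 8.0)
                even_prod = new
            if i >= 2 and (6.0 * odd_prod + 2.0 * even_prod) / 8.0 < 1e-12:
                break
            i += 1
        return QueryDistribution(levels, 1.0 - sum(levels))
    for i, r in enumerate(rs, start=1):
        if i % 2 == 1:
            new = odd_prod * C**r
            levels.append(6.0 * (odd_prod - new) / 8.0)
            odd_prod = new
        else:
            new = even_prod * C**r
            levels.append(2.0 * (even_prod - new) / 8.0)
            even_prod = new
    return QueryDistribution(levels, 1.0 - sum(levels))


# ---------------------------------------------------------------------------
# model tables

_KS = (16, 32, 64, 128)


def table1(ks: Sequence[int] = _KS) -> list[dict]:
    """Optimal r and bits/k-mer for t=4 and t=6, plus the t=1 baseline."""
    rows = []
    for k in ks:
        r4, b4 = optimize_r(4, k)
        r6, b6 = optimize_r(6, k)
        rows.append(
            {
                "k": k,
                "r_t4": round(r4, 3),
                "bits_t4": round(b4, 3),
                "r_t6": round(r6, 3),
                "bits_t6": round(b6, 3),
                "bits_t1": round(baseline_t1(k), 3),
            }
        )
    return rows


def table2(ks: Sequence[int] = _KS) -> list[dict]:
    """Per-filter-ratio optimum vs the single-ratio optimum at t=4."""
    rows = []
    for k in ks:
        ratios, bits_vec = optimize_vector(4, k)
        _, bits_single = optimize_r(4, k)
        rows.append(
            {
                "k": k,
                "ratios": [round(r, 3) for r in ratios],
                "bits_vector": round(bits_vec, 3),
                "bits_single": round(bits_single, 3),
            }
        )
    return rows


def table3(r: float = 5.464, n_levels: int = 4) -> list[dict]:
    """Resolved-query fractions of the first filters, infinite cascade."""
    qd = query_distribution(r, t=math.inf)
    return [
        {"filter": f"B{i+1}", "fraction_pct": round(100 * qd.levels[i], 2)}
        for i in range(n_levels)
    ]


def table4(k: int = 32, ts: Sequence[int] = (1, 2, 4)) -> list[dict]:
    """Per-level resolved fractions at the optimal ratio for t=1, 2, 4."""
    rows = []
    for t in ts:
        r, _ = optimize_r(t, k)
        qd = query_distribution(r, t=t)
        row = {"t": t, "r": round(r, 3)}
        for i in range(max(ts)):
            row[f"B{i+1}_pct"] = round(100 * qd.levels[i], 2) if i < t else 0.0
        row["residual_pct"] = round(100 * qd.residual, 2)
        rows.append(row)
    return rows


def _write_csv(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        for row in rows:
            writer.writerow(
                {
                    key: (" ".join(map(str, v)) if isinstance(v, list) else v)
                    for key, v in row.items()
                }
            )


def _pretty(rows: list[dict]) -> str:
    cols = list(rows[0].keys())
    cells = [[str(r[c]) for c in cols] for r in rows]
    widths = [max(len(c), *(len(row[i]) for row in cells)) for i, c in enumerate(cols)]
    lines = ["  ".join(c.ljust(w) for c, w in zip(cols, widths))]
    for row in cells:
        lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)))
    return "\n".join(lines)


def render_tables(outdir=None) -> dict[str, list[dict]]:
    """Regenerate the four model tables; optionally write CSVs to ``outdir``."""
    tables = {
        "table1": table1(),
        "table2": table2(),
        "table3": table3(),
        "table4": table4(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, rows in tables.items():
            _write_csv(outdir / f"{name}.csv", rows)
    return tables


def pretty_tables(tables: Optional[dict] = None) -> str:
    tables = tables if tables is not None else render_tables()
    out = []
    for name, rows in tables.items():
        out.append(f"== {name} ==")
        out.append(_pretty([{k: (" ".join(map(str, v)) if isinstance(v, list) else v)
                             for k, v in r.items()} for r in rows]))
        out.append("")
    return "\n".join(out)
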