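"""Synthetic genomes and read sets for building and testing the structure.

Emulates, at desk scale, the regime of a short-read sequencing
experiment: a random genome, uniformly placed fixed-length reads from
either strand at a chosen fold-coverage, and i.i.d. per-base
substitution errors (no indels — substitutions already produce the
spurious k-mers the abundance cutoff and the cascade must absorb).
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimConfig", "random_genome", "simulate_reads", "write_fasta", "write_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Defaults emulate a small high-coverage bacterial-style experiment:
    100 bp reads, substitution rate 1%, cutoff d=2 (k-mers kept when seen
    at least 3 times), k=21."""

    genome_length: int = 100_000
    read_length: int = 100
    coverage: float = 50.0
    error_rate: float = 0.01
    seed: int = 1
    k: int = 21
    d: int = 2

    def __post_init__(self):
        if self.genome_length < self.k:
            raise ValueError("genome_length must be >= k")
        if self.read_length < self.k:
            raise ValueError("read_length must be >= k")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


def random_genome(length: int, seed: int = 1) -> str:
    """Uniform i.i.d. ACGT string of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def simulate_reads(
    genome: str,
    read_length: int = 100,
    coverage: float = 50.0,
    error_rate: float = 0.01,
    seed: int = 1,
) -> list[str]:
    """Uniformly placed, random-strand reads with substitution errors.

    The read count is ``round(coverage * len(genome) / read_length)`` so
    total sequenced bases ~ coverage-fold the genome.
    """
    if read_length > len(genome):
        raise ValueError("read_length must be <= genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(genome) / read_length))
    gbytes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    gvals = np.zeros(len(gbytes), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        gvals[gbytes == b] = i
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = []
    for s, rev in zip(starts, strands):
        vals = gvals[s : s + read_length].copy()
        if rev:
            vals = 3 - vals[::-1]  # reverse complement in 2-bit space
        errs = np.nonzero(rng.random(read_length) < error_rate)[0]
        if len(errs):
            # substitute with a uniformly chosen *different* base
            vals[errs] = (vals[errs] + rng.integers(1, 4, size=len(errs))) % 4
        reads.append(_BASES[vals].tobytes().decode("ascii"))
    return reads


def write_fasta(path, sequences, prefix: str = "seq") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(sequences, str):
        sequences = [sequences]
    records = [
        SeqRecord(Seq(s), id=f"{prefix}{i}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, reads, prefix: str = "read") -> None:
    """FASTQ with constant quality 'I' (Q40); qualities are ignored downstream."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, s in enumerate(reads):
        rec = SeqRecord(Seq(s), id=f"{prefix}{i}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
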