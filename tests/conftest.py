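import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bloomcascade.kmers import KmerSet, count_kmers
from bloomcascade.simulate import random_genome

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def genome_kmer_set(n_kmers: int, k: int, seed: int) -> KmerSet:
    """Node set of a path-like de Bruijn graph: the k-mers of one random
    genome, sized so ~n_kmers are distinct (collisions are negligible at
    these scales)."""
    genome = random_genome(n_kmers + k - 1, seed=seed)
    return count_kmers([genome], k, d=0)


@pytest.fixture(scope="session")
def path_set_10k() -> KmerSet:
    return genome_kmer_set(10_000, 21, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140224)
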