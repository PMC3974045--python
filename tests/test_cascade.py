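"""Cascade construction, exact membership under the contract, round-trips."""

import numpy as np
import pytest

from bloomcascade.cascade import CascadingDBG, QueryStats, build
from bloomcascade.estimator import C
from bloomcascade.kmers import Kmer, KmerSet, count_kmers, neighbor_matrix, potential_neighbors
from bloomcascade.simulate import random_genome

from conftest import genome_kmer_set


def contract_probes(t0: KmerSet) -> np.ndarray:
    """All T0 members plus all their potential neighbors (the only
    k-mers a traversal may ever query)."""
    nbrs = np.unique(neighbor_matrix(t0.codes, t0.k).ravel())
    return np.unique(np.concatenate([t0.codes, nbrs]))


class TestBuild:
    def test_tiny_set_with_generous_ratio_is_plainly_exact(self):
        """At r=20 the FP rate is ~1e-4, so T1 is almost surely empty
        and the single filter plus residual reproduces the exact set."""
        t0 = count_kmers(["ACGTACGT"], 3, d=0)
        g = build(t0, t=1, ratios=20.0)
        assert g.level_sizes[1] == 0
        probes = contract_probes(t0)
        truth = t0.contains_many(probes)
        ans = np.array([g.query(int(c)) for c in probes])
        assert np.array_equal(ans, truth)

    def test_level_set_inclusions(self):
        """T0 and T1 are disjoint; T2 <= T0, T3 <= T1, T4 <= T2 both as
        inclusions and hence in size."""
        t0 = genome_kmer_set(5_000, 15, seed=7)
        g = build(t0, t=4, ratios=4.0)  # small r so every level is populated
        sizes = g.level_sizes
        assert sizes[0] == len(t0)
        assert sizes[2] <= sizes[0] and sizes[3] <= sizes[1] and sizes[4] <= sizes[2]
        # recompute the level sets to check the actual inclusions
        b1, b2, b3, b4 = g.filters
        cand = np.unique(neighbor_matrix(t0.codes, t0.k).ravel())
        in_b1 = cand[b1.contains_many(cand)]
        t1 = np.setdiff1d(in_b1, t0.codes)
        assert len(np.intersect1d(t1, t0.codes)) == 0
        t2 = t0.codes[b2.contains_many(t0.codes)]
        t3 = t1[b3.contains_many(t1)]
        t4 = t2[b4.contains_many(t2)]
        assert len(t1) == sizes[1] and len(t2) == sizes[2]
        assert np.isin(t3, t1).all() and np.isin(t4, t2).all()
        assert np.array_equal(np.sort(t4), np.sort(g.residual))

    def test_t1_size_tracks_6N_c_to_r(self):
        """|T1| concentrates around the 6N c^r estimate (six of the
        eight extensions of a path node are potential false positives)."""
        t0 = genome_kmer_set(30_000, 21, seed=11)
        r = 6.049
        g = build(t0, t=4, ratios=r)
        expected = 6 * len(t0) * C**r
        assert 0.5 * expected <= g.level_sizes[1] <= 1.5 * expected

    def test_degenerate_empty_level(self):
        """A huge ratio empties T1; deeper filters degenerate to 1 bit
        and all later levels stay empty, queries remain exact."""
        t0 = count_kmers(["ACGTACGTACGTAAAT"], 5, d=0)
        g = build(t0, t=4, ratios=50.0)
        assert g.level_sizes[1:] == [0, 0, 0, 0]
        assert all(f.m == 1 for f in g.filters[1:])
        probes = contract_probes(t0)
        assert np.array_equal(
            np.array([g.query(int(c)) for c in probes]), t0.contains_many(probes)
        )

    def test_build_determinism(self):
        t0 = genome_kmer_set(2_000, 21, seed=3)
        a = build(t0, t=2, master_seed=123)
        b = build(t0, t=2, master_seed=123)
        assert a.level_sizes == b.level_sizes
        assert all(x == y for x, y in zip(a.filters, b.filters))
        assert np.array_equal(a.residual, b.residual)

    def test_partitioned_construction_matches_in_memory(self):
        t0 = genome_kmer_set(3_000, 21, seed=5)
        a = build(t0, t=2, master_seed=9)
        b = build(t0, t=2, master_seed=9, partitions=4)
        assert a.level_sizes == b.level_sizes
        assert np.array_equal(a.residual, b.residual)

    def test_input_validation(self):
        t0 = count_kmers(["ACGTACGT"], 3, d=0)
        with pytest.raises(ValueError):
            build(t0, t=0)
        with pytest.raises(ValueError):
            build(t0, t=2, ratios=[5.0])
        with pytest.raises(ValueError):
            build(t0, t=1, ratios=-1.0)


class TestQueryExactness:
    @pytest.mark.parametrize("k", [15, 21, 31])
    @pytest.mark.parametrize("t", [1, 2, 4])
    def test_exact_on_all_contract_probes(self, k, t):
        """query() agrees with the exact-set oracle on 100% of
        contract-valid probes, for every truncation parity."""
        t0 = genome_kmer_set(1_000, k, seed=k * 10 + t)
        g = build(t0, t=t, ratios=4.0)  # low r: plenty of false positives to cascade
        probes = contract_probes(t0)
        truth = t0.contains_many(probes)
        ans, _ = g.query_many(probes)
        assert np.array_equal(ans, truth)

    def test_wide_k_scalar_path_exact(self):
        t0 = genome_kmer_set(300, 33, seed=8)
        g = build(t0, t=2, ratios=6.0)
        probes = contract_probes(t0)
        truth = np.array([t0.contains(int(c)) for c in probes])
        ans = np.array([g.query(int(c)) for c in probes])
        assert np.array_equal(ans, truth)

    def test_parity_rule_on_stats(self):
        """A query resolved at an even filter level is a member; at an
        odd level a non-member (first-no parity of the cascade)."""
        t0 = genome_kmer_set(2_000, 21, seed=13)
        g = build(t0, t=4, ratios=4.0)
        probes = contract_probes(t0)
        ans, levels = g.query_many(probes)
        for j in range(1, 5):
            at_j = levels == j
            if at_j.any():
                assert (ans[at_j] == (j % 2 == 0)).all()

    def test_scalar_and_vector_queries_agree(self):
        t0 = genome_kmer_set(1_000, 21, seed=17)
        g = build(t0, t=4, ratios=4.0)
        probes = contract_probes(t0)[:500]
        vec, _ = g.query_many(probes)
        scal = np.array([g.query(int(c)) for c in probes])
        assert np.array_equal(vec, scal)

    def test_stats_accounting(self):
        t0 = genome_kmer_set(1_000, 21, seed=19)
        g = build(t0, t=2, ratios=5.0)
        stats = QueryStats()
        probes = contract_probes(t0)
        g.query_many(probes, stats=stats)
        assert stats.total == len(probes)
        scalar_stats = QueryStats()
        for c in probes[:100]:
            g.query(int(c), stats=scalar_stats)
        assert scalar_stats.total == 100

    def test_k_mismatch_rejected(self):
        t0 = genome_kmer_set(500, 21, seed=1)
        g = build(t0, t=1)
        with pytest.raises(ValueError, match="k mismatch"):
            g.query(Kmer(0, 15))


class TestNeighborsInGraph:
    def test_interior_path_node_has_two_neighbors(self):
        from bloomcascade import encode

        genome = random_genome(5_000, seed=21)
        t0 = count_kmers([genome], 21, d=0)
        g = build(t0, t=4)
        nbrs = g.neighbors_in_graph(encode(genome[100:121]))
        assert len(nbrs) == 2
        true_set = {encode(genome[99:120]).code, encode(genome[101:122]).code}
        assert {v.code for v in nbrs} == true_set

    def test_isolated_kmer_has_no_neighbors(self):
        from bloomcascade import encode

        t0 = KmerSet.from_codes(21, [encode("A" * 10 + "CGT" + "G" * 8).code])
        g = build(t0, t=2, ratios=12.0)
        u = next(iter(t0))
        nbrs = g.neighbors_in_graph(u)
        brute = [v for v in potential_neighbors(u) if v in t0]
        assert {v.code for v in nbrs} == {v.code for v in brute}

    def test_result_is_subset_of_potential(self):
        t0 = genome_kmer_set(1_000, 15, seed=23)
        g = build(t0, t=2)
        u = next(iter(t0))
        nbrs = g.neighbors_in_graph(u)
        pot = {v.code for v in potential_neighbors(u)}
        assert len(nbrs) <= 8 and {v.code for v in nbrs} <= pot


class TestSerialization:
    def test_save_load_save_identical_bytes(self, tmp_path):
        t0 = genome_kmer_set(2_000, 21, seed=29)
        g = build(t0, t=4)
        p1, p2 = tmp_path / "a.cdbg", tmp_path / "b.cdbg"
        g.save(p1)
        CascadingDBG.load(p1).save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_queries_identical_after_roundtrip(self, tmp_path):
        t0 = genome_kmer_set(2_000, 21, seed=31)
        g = build(t0, t=3)  # odd t exercises the inverted residual rule
        p = tmp_path / "g.cdbg"
        g.save(p)
        h = CascadingDBG.load(p)
        probes = contract_probes(t0)[:1000]
        a, _ = g.query_many(probes)
        b, _ = h.query_many(probes)
        assert np.array_equal(a, b)

    def test_truncated_and_corrupted_files_rejected(self, tmp_path):
        t0 = genome_kmer_set(500, 21, seed=37)
        g = build(t0, t=2)
        p = tmp_path / "g.cdbg"
        g.save(p)
        blob = p.read_bytes()
        (tmp_path / "t.cdbg").write_bytes(blob[: len(blob) // 3])
        with pytest.raises(ValueError, match="truncated"):
            CascadingDBG.load(tmp_path / "t.cdbg")
        corrupt = bytearray(blob)
        corrupt[60] ^= 0xFF  # flip a bit inside B1's bitmap
        (tmp_path / "c.cdbg").write_bytes(bytes(corrupt))
        with pytest.raises(ValueError, match="checksum"):
            CascadingDBG.load(tmp_path / "c.cdbg")

    def test_wide_k_roundtrip(self, tmp_path):
        t0 = genome_kmer_set(200, 33, seed=41)
        g = build(t0, t=2, ratios=6.0)
        p = tmp_path / "w.cdbg"
        g.save(p)
        h = CascadingDBG.load(p)
        probes = contract_probes(t0)
        assert [g.query(int(c)) for c in probes] == [h.query(int(c)) for c in probes]


def test_report_mentions_all_components():
    t0 = genome_kmer_set(1_000, 21, seed=43)
    g = build(t0, t=2)
    rep = g.report()
    assert "B1" in rep and "B2" in rep and "T2 table" in rep and "bits/k-mer" in rep
    bits = g.bits_used()
    assert bits["total"] == sum(bits["filters"]) + bits["residual"]
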