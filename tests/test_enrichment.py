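import math

import numpy as np
import pandas as pd
import pytest

import popstruct as ps
from popstruct.core_io import InputError
from popstruct.enrichment import correlation_distance_matrix


class TestSignedScore:
    def test_enriched_tail(self):
        # x=4 of n=4 from pool K=5/N=10: p = C(5,4)/C(10,4) = 5/210
        score = ps.hypergeom_signed_score(4, 4, 5, 10)
        assert score == pytest.approx(-math.log10(5 / 210), abs=1e-9)
        assert score > 0

    def test_depleted_tail_is_mirror(self):
        score = ps.hypergeom_signed_score(0, 4, 5, 10)
        assert score == pytest.approx(math.log10(5 / 210), abs=1e-9)
        assert score < 0

    def test_zero_at_expectation(self):
        assert ps.hypergeom_signed_score(2, 4, 5, 10) == 0.0

    def test_monomorphic_pool_zero(self):
        assert ps.hypergeom_signed_score(4, 4, 10, 10) == 0.0
        assert ps.hypergeom_signed_score(0, 4, 0, 10) == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InputError):
            ps.hypergeom_signed_score(5, 4, 5, 10)

    def test_magnitude_increases_away_from_expectation(self):
        # N=40, K=20, n=10 -> expectation 5
        scores = [ps.hypergeom_signed_score(x, 10, 20, 40) for x in range(11)]
        for x in range(5, 10):
            assert scores[x + 1] > scores[x] >= 0
        for x in range(5, 0, -1):
            assert scores[x - 1] < scores[x] <= 0

    def test_antisymmetric_under_allele_complement(self):
        # scoring the non-risk allele of a biallelic locus flips the sign
        x, n, K, N = 7, 20, 30, 100
        a = ps.hypergeom_signed_score(x, n, K, N)
        b = ps.hypergeom_signed_score(n - x, n, N - K, N)
        assert a == pytest.approx(-b, abs=1e-9)


class TestEnrichmentMatrix:
    def test_shapes_and_conventions(self, small_dataset):
        gm, h, panel = small_dataset
        ft = ps.allele_frequencies(gm, h, "sub")
        fa = ps.allele_frequencies(gm, h, "all")
        em = ps.enrichment_matrix(ft, fa, panel)
        assert em.scores.shape == (gm.n_loci, 4)
        dev = em.observed - em.expected
        signs_ok = (np.sign(em.scores.to_numpy()) == np.sign(dev.to_numpy())) | (
            dev.to_numpy() == 0
        )
        assert signs_ok.all()
        # |score| = -log10(p)
        np.testing.assert_allclose(
            np.abs(em.scores.to_numpy()), -np.log10(em.pvalues.to_numpy()), atol=1e-9
        )

    def test_partition_counting_identity(self, small_dataset):
        # populations partition the pool: deviations sum to zero per locus
        gm, h, panel = small_dataset
        ft = ps.allele_frequencies(gm, h, "sub")
        fa = ps.allele_frequencies(gm, h, "all")
        em = ps.enrichment_matrix(ft, fa, panel)
        dev = (em.observed - em.expected).sum(axis=1)
        np.testing.assert_allclose(dev.to_numpy(), 0.0, atol=1e-9)

    def test_fixed_subpopulation_scores_high(self):
        # one pop fixed for risk allele, other at ~0 -> pool near 0.5
        codes = np.zeros((40, 1, 2), dtype=np.int8)
        codes[20:] = 1
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(40)], ["rs1"], [("A", "G")], codes)
        h = ps.PopulationHierarchy(gm.samples, ["HI"] * 20 + ["LO"] * 20, ["X"] * 40)
        panel = ps.SnpPanel([ps.SnpRecord("rs1", "1p1", "A", ("G",), 2.0)])
        em = ps.enrichment_matrix(
            ps.allele_frequencies(gm, h, "sub"), ps.allele_frequencies(gm, h, "all"), panel
        )
        assert em.scores.loc["rs1", "HI"] > 5
        assert em.scores.loc["rs1", "LO"] < -5


def upgma_oracle(d):
    """Naive average-linkage agglomeration; returns sorted merge heights."""
    d = d.astype(float).copy()
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    dist = {(i, j): d[i, j] for i in range(d.shape[0]) for j in range(i + 1, d.shape[0])}
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        new = max(max(clusters, default=-1), i, j) + 1
        for k in clusters:
            members = clusters[k]
            dist[(min(k, new), max(k, new))] = np.mean(
                [d[a, b] for a in merged for b in members]
            )
        clusters[new] = merged
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
    return sorted(heights)


class TestClusterOrder:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, -1.0, 0.5]],
            index=["a", "b", "c"],
        )
        # rows a and b are perfectly correlated (distance 0)
        order, Z = ps.cluster_order(m, "rows")
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1  # the zero-distance pair stays adjacent

    def test_anticorrelated_row_joins_last(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.1, 2.1, 3.2], [-1.0, -2.0, -3.0]],
            index=["r1", "r2", "r3"],
        )
        order, Z = ps.cluster_order(m, "rows")
        assert order[-1] == "r3" or order[0] == "r3"
        assert set(order[:2]) == {"r1", "r2"} or set(order[1:]) == {"r1", "r2"}

    def test_merge_heights_match_upgma_oracle(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.normal(size=(6, 8)))
        d = correlation_distance_matrix(m.to_numpy())
        _, Z = ps.cluster_order(m, "rows")
        np.testing.assert_allclose(sorted(Z[:, 2]), upgma_oracle(d), atol=1e-10)

    def test_invariant_to_positive_row_scaling(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.normal(size=(5, 7)))
        scaled = m * 3.7
        o1, _ = ps.cluster_order(m, "rows")
        o2, _ = ps.cluster_order(scaled, "rows")
        assert o1 == o2

    def test_zero_variance_row_handled(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        d = correlation_distance_matrix(m.to_numpy())
        assert d[0, 1] == 2.0 and d[0, 2] == 2.0
        order, _ = ps.cluster_order(m, "rows")
        assert len(order) == 3
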