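import math

import numpy as np
import pytest
from scipy import stats

import popstruct as ps
from popstruct.core_io import MISSING
from popstruct.differentiation import (
    McParams,
    _enumerate_tail,
    _enumerate_tail_2x2,
    genic_table,
    genotypic_table,
)
from conftest import random_genotype_matrix


# ---------------------------------------------------------------------------
# Brute-force AMOVA oracle: explicit pairwise allele-distance matrix
# ---------------------------------------------------------------------------

def amova_oracle(gm, labels):
    """Variance components from the full 0/1 allele distance matrix."""
    sig_a = np.full(gm.n_loci, np.nan)
    sig_w = np.full(gm.n_loci, np.nan)
    for l in range(gm.n_loci):
        pops, alleles = [], []
        for i, lab in enumerate(labels):
            a, b = gm.codes[i, l]
            if a == MISSING:
                continue
            pops += [lab, lab]
            alleles += [int(a), int(b)]
        alleles = np.asarray(alleles)
        pops = np.asarray(pops)
        uniq = list(dict.fromkeys(pops))
        N, P = len(alleles), len(uniq)
        if P < 2 or N - P < 1:
            continue
        d2 = (alleles[:, None] != alleles[None, :]).astype(float)
        iu = np.triu_indices(N, k=1)
        ss_total = d2[iu].sum() / N
        ss_within = 0.0
        n_p = []
        for pop in uniq:
            sel = np.nonzero(pops == pop)[0]
            n_p.append(len(sel))
            sub = d2[np.ix_(sel, sel)]
            ss_within += sub[np.triu_indices(len(sel), k=1)].sum() / len(sel)
        n_p = np.asarray(n_p, dtype=float)
        ss_among = ss_total - ss_within
        df_a, df_w = P - 1, N - P
        ms_w = ss_within / df_w
        n0 = (N - (n_p**2).sum() / N) / df_a
        if n0 <= 0:
            continue
        sig_a[l] = (ss_among / df_a - ms_w) / n0
        sig_w[l] = ms_w
    ok = np.isfinite(sig_a)
    if not ok.any():
        return float("nan"), sig_a, sig_w
    fst = sig_a[ok].sum() / (sig_a[ok] + sig_w[ok]).sum()
    return fst, sig_a, sig_w


class TestAmovaFst:
    def test_fixed_differences_give_fst_one(self):
        codes = np.array([[[0, 0]]] * 5 + [[[1, 1]]] * 5, dtype=np.int8)
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(10)], ["rs1"], [("A", "T")], codes)
        res = ps.amova_fst(gm, ["P1"] * 5 + ["P2"] * 5)
        assert res.fst == pytest.approx(1.0, abs=1e-12)

    def test_worked_two_population_example_matches_oracle(self):
        # pop1: alleles 8 A / 2 T; pop2: 2 A / 8 T (5 diploid each)
        codes1 = np.array([[[0, 0]]] * 4 + [[[0, 1]]] * 0 + [[[1, 1]]] * 1, dtype=np.int8)
        codes2 = np.array([[[0, 0]]] * 1 + [[[1, 1]]] * 4, dtype=np.int8)
        codes = np.concatenate([codes1, codes2])
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(10)], ["rs1"], [("A", "T")], codes)
        labels = ["P1"] * 5 + ["P2"] * 5
        res = ps.amova_fst(gm, labels)
        oracle_fst, _, _ = amova_oracle(gm, labels)
        assert res.fst_raw == pytest.approx(oracle_fst, abs=1e-12)
        assert 0 < res.fst < 1

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            gm, labels = random_genotype_matrix(
                rng,
                n_pops=int(rng.integers(2, 5)),
                n_ind=int(rng.integers(3, 21)),
                n_loci=int(rng.integers(1, 4)),
            )
            res = ps.amova_fst(gm, labels)
            oracle_fst, _, _ = amova_oracle(gm, labels)
            if math.isnan(oracle_fst):
                assert math.isnan(res.fst_raw)
            else:
                assert res.fst_raw == pytest.approx(oracle_fst, abs=1e-10)

    def test_per_locus_matches_oracle(self):
        rng = np.random.default_rng(8)
        gm, labels = random_genotype_matrix(rng, n_pops=3, n_ind=12, n_loci=3)
        res = ps.amova_fst(gm, labels)
        _, sig_a, sig_w = amova_oracle(gm, labels)
        for l, loc in enumerate(gm.loci):
            if np.isfinite(sig_a[l]) and (sig_a[l] + sig_w[l]) != 0:
                assert res.per_locus_fst_raw[loc] == pytest.approx(
                    sig_a[l] / (sig_a[l] + sig_w[l]), abs=1e-10
                )

    def test_null_populations_not_significant(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 2, size=(400, 1, 2)).astype(np.int8)
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(400)], ["rs1"], [("A", "T")], codes)
        res = ps.amova_fst(gm, ["P1"] * 200 + ["P2"] * 200, n_permutations=199, rng=rng)
        assert res.fst >= 0.0
        assert res.p_value > 0.01

    def test_monomorphic_locus_undefined(self):
        codes = np.zeros((6, 1, 2), dtype=np.int8)
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(6)], ["rs1"], [("A", "T")], codes)
        res = ps.amova_fst(gm, ["P1"] * 3 + ["P2"] * 3)
        assert math.isnan(res.per_locus_fst["rs1"])

    def test_permutation_p_bounded_below(self):
        rng = np.random.default_rng(5)
        gm, labels = random_genotype_matrix(rng, n_pops=2, n_ind=10, n_loci=1)
        res = ps.amova_fst(gm, labels, n_permutations=99, rng=rng)
        assert res.p_value >= 1 / 100


class TestWeirCockerham:
    def test_agrees_with_amova_on_clear_structure(self):
        cfg = ps.SimulationConfig(
            n_superpops=2, subpops_per_superpop=1, samples_per_subpop=300,
            n_loci=50, fst_between_superpops=0.1, fst_within_superpop=0.0, seed=21,
        )
        gm, h, _ = ps.simulate_dataset(cfg)
        labels = h.labels("super", gm.samples)
        amova = ps.amova_fst(gm, labels).fst_raw
        wc = ps.weir_cockerham_fst(gm, labels)
        assert wc == pytest.approx(amova, rel=0.15)


class TestNeiDistance:
    def test_identical_tables_zero(self):
        f = {"rs1": np.array([0.3, 0.7]), "rs2": np.array([0.5, 0.5])}
        assert ps.nei_distance(f, f) == pytest.approx(0.0, abs=1e-15)

    def test_worked_one_locus_value(self):
        x = {"rs1": np.array([1.0, 0.0])}
        y = {"rs1": np.array([0.5, 0.5])}
        assert ps.nei_distance(x, y) == pytest.approx(0.5 * math.log(2), abs=1e-12)

    def test_disjoint_fixation_infinite(self):
        x = {"rs1": np.array([1.0, 0.0]), "rs2": np.array([1.0, 0.0])}
        y = {"rs1": np.array([0.0, 1.0]), "rs2": np.array([0.0, 1.0])}
        assert ps.nei_distance(x, y) == math.inf

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet([1, 1, 1], size=2)
        q = rng.dirichlet([1, 1, 1], size=2)
        x = {"rs1": p[0], "rs2": p[1]}
        y = {"rs1": q[0], "rs2": q[1]}
        assert ps.nei_distance(x, y) == pytest.approx(ps.nei_distance(y, x), abs=1e-15)
        perm = [2, 0, 1]
        xp = {k: v[perm] for k, v in x.items()}
        yp = {k: v[perm] for k, v in y.items()}
        assert ps.nei_distance(xp, yp) == pytest.approx(ps.nei_distance(x, y), abs=1e-12)

    def test_matrix_from_freqtable(self, small_dataset):
        gm, h, _ = small_dataset
        ft = ps.allele_frequencies(gm, h, "sub")
        m = ps.nei_distance_matrix(ft)
        assert m.kind == "nei"
        assert (np.diag(m.values) == 0).all()
        assert (m.values >= 0).all()


class TestExactGTest:
    def test_diagonal_2x2_enumeration(self):
        p, se = ps.exact_g_test(np.array([[2, 0], [0, 2]]))
        assert p == pytest.approx(1 / 3, abs=1e-12)
        assert se == 0.0

    def test_minimal_g_table_p_one(self):
        p, _ = ps.exact_g_test(np.array([[2, 2], [2, 2]]))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        p, se = ps.exact_g_test(np.array([[3, 4], [0, 0]]))
        assert math.isnan(p) and math.isnan(se)

    def test_g_statistic_matches_scipy(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 20, size=(3, 4))
        g, _, _, _ = stats.chi2_contingency(t, correction=False, lambda_="log-likelihood")
        assert ps.g_statistic(t) == pytest.approx(g, rel=1e-10)

    def test_general_enumeration_matches_2x2_shortcut(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert _enumerate_tail(t) == pytest.approx(_enumerate_tail_2x2(t), abs=1e-12)

    def test_mc_within_3se_of_enumeration(self):
        rng = np.random.default_rng(6)
        mc = McParams(dememorization=3000, batches=30, iterations_per_batch=1000)
        for total in (60, 200, 480):
            t = rng.multinomial(total, [0.3, 0.2, 0.3, 0.2]).reshape(2, 2)
            exact = _enumerate_tail_2x2(t)
            p, se = ps.exact_g_test(t, mc_params=mc, rng=rng, force_mc=True)
            se_floor = math.sqrt(max(exact * (1 - exact), 1e-12) / (mc.batches * mc.iterations_per_batch))
            assert abs(p - exact) <= 3 * max(se, se_floor)

    def test_genic_and_genotypic_tables(self, small_dataset):
        gm, h, _ = small_dataset
        labels = h.labels("super", gm.samples)
        tg = genic_table(gm, labels, 0)
        assert tg.sum() == (~gm.missing_mask()[:, 0]).sum() * 2
        tt = genotypic_table(gm, labels, 0)
        assert tt.sum() == (~gm.missing_mask()[:, 0]).sum()

    def test_full_differentiation_run(self, small_dataset):
        gm, h, _ = small_dataset
        mc = McParams(dememorization=500, batches=10, iterations_per_batch=200)
        res = ps.differentiation_exact_tests(
            gm, h, "super", "genic", mc, np.random.default_rng(0)
        )
        assert res.df == 2 * sum(1 for v in res.per_locus_p.values() if not math.isnan(v))
        assert 0 <= res.p <= 1


class TestFisherCombination:
    def test_single_locus(self):
        chi2, df, p = ps.combine_fisher([0.5])
        assert chi2 == pytest.approx(2 * math.log(2), abs=1e-12)
        assert df == 2

    def test_all_ones(self):
        chi2, df, p = ps.combine_fisher([1.0] * 5)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_32_loci_closed_form(self):
        chi2, df, p = ps.combine_fisher([0.5] * 32)
        assert chi2 == pytest.approx(64 * math.log(2), abs=1e-9)
        assert df == 64
        assert p == pytest.approx(stats.chi2.sf(64 * math.log(2), 64), abs=1e-12)
        assert p == pytest.approx(0.97, abs=0.01)

    def test_zero_p_marker(self):
        chi2, df, p = ps.combine_fisher([0.0, 0.5])
        assert chi2 == math.inf and p == 0.0

    def test_nan_excluded(self):
        chi2, df, p = ps.combine_fisher([float("nan"), 0.5])
        assert df == 2


class TestPairwiseAndPerLocus:
    def test_matrix_shape_and_symmetry(self, small_dataset):
        gm, h, _ = small_dataset
        m, pmat = ps.pairwise_fst(gm, h, "sub", n_permutations=0)
        assert m.values.shape == (4, 4)
        assert np.allclose(m.values, m.values.T)
        assert (np.diag(m.values) == 0).all()
        assert ((m.values >= 0) & (m.values <= 1)).all()

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(10)
        codes = rng.integers(0, 2, size=(300, 2, 2)).astype(np.int8)
        gm = ps.GenotypeMatrix([f"S{i}" for i in range(300)], ["rs1", "rs2"], [("A", "T")] * 2, codes)
        h = ps.PopulationHierarchy(gm.samples, ["P1"] * 100 + ["P2"] * 100 + ["P3"] * 100, ["X"] * 300)
        m, _ = ps.pairwise_fst(gm, h, "sub", n_permutations=0)
        off = m.values[np.triu_indices(3, k=1)]
        assert (off < 0.02).all()

    def test_per_locus_global_fst(self, small_dataset):
        gm, h, _ = small_dataset
        plf = ps.per_locus_global_fst(gm, h, "super")
        assert set(plf) == set(gm.loci)
        vals = [v for v in plf.values() if not math.isnan(v)]
        assert all(0 <= v <= 1 for v in vals)
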