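"""Dissimilarities, PCA, fit correlation, FST, geographic and Mantel tests."""

import numpy as np
import pandas as pd
import pytest

import migscape as ms

from test_prep import make_panel, random_panel


class TestObservedDissimilarity:
    def test_identical_rows_zero(self):
        g = make_panel(np.array([[0, 1, 2, 1], [0, 1, 2, 1]]))
        D = ms.observed_dissimilarity(g)
        assert D[0, 1] == 0.0

    def test_opposite_homozygotes_single_snp(self):
        g = make_panel(np.array([[0], [2]]))
        assert ms.observed_dissimilarity(g)[0, 1] == 4.0

    def test_pairwise_complete_rule(self):
        g = make_panel(np.array([[0, -1, 2], [0, 1, 2]]))
        assert ms.observed_dissimilarity(g)[0, 1] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        g = random_panel(rng, 12, 80)
        mask = rng.random(g.calls.shape) < 0.1
        g.calls[mask] = -1
        D = ms.observed_dissimilarity(g)
        for i in range(12):
            for j in range(i + 1, 12):
                shared = (g.calls[i] != -1) & (g.calls[j] != -1)
                diffs = (g.calls[i, shared].astype(float)
                         - g.calls[j, shared].astype(float)) ** 2
                assert abs(D[i, j] - diffs.mean()) < 1e-12

    def test_zero_shared_loci_names_pair(self):
        calls = np.array([[0, -1], [-1, 2], [1, 1]])
        g = make_panel(calls)
        with pytest.raises(ValueError, match="s0.*s1|s1.*s0"):
            ms.observed_dissimilarity(g)


class TestPca:
    def test_rank_one_matrix(self):
        base = np.array([0, 0, 2, 2, 2])
        calls = np.tile(base[:, None], (1, 30))
        g = make_panel(calls)
        res = ms.pca_decompose(g, 2)
        assert res.eigenvalues[0] > 0
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(1)
        g = random_panel(rng, 40, 200)
        a = ms.pca_decompose(g, 5)
        b = ms.pca_decompose(g, 5)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_two_population_separation(self, small_grid):
        # low migration between two halves -> PC1 separates them cleanly
        g2 = ms.DemeGraph(np.array([[0.0, 0], [1, 0]]), [[0, 1]], 1.0)
        field = ms.make_rate_field(g2)
        cfg = ms.SimConfig(deme_size=50, p_snps=1000, n_generations=300,
                           base_m=0.0005, n_sampled_per_deme=25, seed=5)
        geno = ms.simulate_wf_genotypes(field, cfg)
        res = ms.pca_decompose(geno, 2)
        pop = geno.samples["pop"].to_numpy()
        pc1_a = res.scores[pop == "deme0", 0]
        pc1_b = res.scores[pop == "deme1", 0]
        assert pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()

    def test_all_missing_snp_raises(self):
        g = make_panel(np.array([[0, -1], [1, -1], [2, -1]]))
        with pytest.raises(ValueError):
            ms.pca_decompose(g, 1)


class TestExpectedDistanceFromPcs:
    def test_point_population_median_is_the_point(self):
        scores = np.array([[1.0, 2], [1, 2], [5, 6]])
        pops = np.array(["a", "a", "b"])
        mat, labels = ms.expected_distance_from_pcs(scores, pops, 2)
        assert mat[0, 1] == pytest.approx((5 - 1) ** 2 + (6 - 2) ** 2)

    def test_full_rank_equals_full_space_distance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(12, 6))
        pops = np.repeat(["a", "b", "c"], 4)
        mat, _ = ms.expected_distance_from_pcs(scores, pops, 6)
        med = np.array([np.median(scores[pops == l], axis=0) for l in ["a", "b", "c"]])
        expected = ((med[:, None] - med[None, :]) ** 2).sum(axis=2)
        np.testing.assert_allclose(mat, expected)

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            ms.expected_distance_from_pcs(np.ones((2, 3)), np.array(["a", "a"]), 5)


class TestFitCorrelation:
    def test_perfect_and_anti_correlation(self):
        rng = np.random.default_rng(3)
        m = rng.random((5, 5))
        m = m + m.T
        np.fill_diagonal(m, 0)
        assert ms.fit_correlation(m, m).pearson_r == pytest.approx(1.0)
        assert ms.fit_correlation(m, -m + 3).pearson_r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        m = np.ones((4, 4))
        with pytest.raises(ValueError):
            ms.fit_correlation(m, m)


class TestFstEmpirical:
    def test_fixed_opposite_alleles_gives_one(self):
        calls = np.r_[np.zeros((10, 20)), np.full((10, 20), 2)].astype(np.int8)
        g = make_panel(calls)
        pops = np.repeat(["a", "b"], 10)
        assert ms.fst_empirical(g, pops) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.2, 0.8, size=3000)
        calls = rng.binomial(2, freqs[None, :], size=(400, 3000)).astype(np.int8)
        g = make_panel(calls)
        pops = np.repeat(["a", "b"], 200)
        assert abs(ms.fst_empirical(g, pops)) < 0.01

    def test_hand_computed_weir_cockerham_toy(self):
        # 2 pops x 10 diploids, one locus, alt-allele counts 15/20 and 5/20
        pop1 = [2, 2, 2, 2, 2, 1, 1, 1, 1, 1]   # 15 alt alleles, 5 hets
        pop2 = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]   # 5 alt alleles, 5 hets
        calls = np.array(pop1 + pop2, dtype=np.int8)[:, None]
        g = make_panel(calls)
        pops = np.repeat(["a", "b"], 10)
        # by-hand variance components (r=2, n_i=10, p=(0.75, 0.25), h=(0.5, 0.5))
        r, n = 2, 10.0
        n_bar, nc = n, n
        p_bar, h_bar = 0.5, 0.5
        s2 = (n * 0.25 ** 2 + n * 0.25 ** 2) / ((r - 1) * n_bar)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / nc) * (s2 - (pq - s2 / 2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (pq - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        assert ms.fst_empirical(g, pops) == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(5)
        g = random_panel(rng, 40, 100)
        pops = np.repeat(["a", "b"], 20)
        f1 = ms.fst_empirical(g, pops)
        swapped = make_panel((2 - g.calls).astype(np.int8))
        assert ms.fst_empirical(swapped, pops) == pytest.approx(f1, abs=1e-12)

    def test_monomorphic_panel_raises(self):
        g = make_panel(np.ones((6, 4), dtype=np.int8) * 2)
        with pytest.raises(ValueError):
            ms.fst_empirical(g, np.repeat(["a", "b"], 3))


class TestFstSteppingStone:
    def test_limits(self):
        assert ms.fst_stepping_stone(1e9) < 1e-6
        assert ms.fst_stepping_stone(1e-12) > 1 - 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ms.fst_stepping_stone(0.0)
        with pytest.raises(ValueError):
            ms.island_kappa(1)


class TestGreatCircle:
    def test_identical_and_antipodal(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [180.0, 0.0]])
        D = ms.great_circle_matrix(pts)
        assert D[0, 1] == 0.0
        assert D[0, 2] == pytest.approx(np.pi * 6371.0, rel=1e-6)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        pts = np.c_[rng.uniform(-180, 180, 8), rng.uniform(-60, 60, 8)]
        D = ms.great_circle_matrix(pts)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)


def _mantel_world(rng, n=15, lang_effect=0.0, noise=0.3):
    pts = rng.uniform(0, 10, size=(n, 2))
    D_geo = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    labels = rng.integers(0, 3, size=n)
    D_lang = (labels[:, None] != labels[None, :]).astype(float)
    E = rng.normal(0, noise, size=(n, n))
    E = (E + E.T) / 2
    D_gen = D_geo + lang_effect * D_lang + E
    np.fill_diagonal(D_gen, 0.0)
    return D_gen, D_lang, D_geo


class TestPartialMantel:
    def test_determinism(self):
        rng = np.random.default_rng(7)
        D_gen, D_lang, D_geo = _mantel_world(rng)
        a = ms.partial_mantel(D_gen, D_lang, D_geo, n_perm=199, seed=3)
        b = ms.partial_mantel(D_gen, D_lang, D_geo, n_perm=199, seed=3)
        assert a.p_value == b.p_value and a.r == b.r

    def test_language_signal_detected(self):
        rng = np.random.default_rng(8)
        D_gen, D_lang, D_geo = _mantel_world(rng, lang_effect=2.0)
        res = ms.partial_mantel(D_gen, D_lang, D_geo, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_reduces_to_simple_mantel_when_geo_constant(self):
        rng = np.random.default_rng(9)
        D_gen, D_lang, _ = _mantel_world(rng)
        D_geo = np.ones_like(D_gen)
        np.fill_diagonal(D_geo, 0.0)
        # residualizing on an (almost) constant geographic matrix leaves
        # the plain correlation of the matrices
        res = ms.partial_mantel(D_gen, D_lang, D_geo * 0 + 1, n_perm=99, seed=2)
        iu = np.triu_indices(len(D_gen), 1)
        r_simple = np.corrcoef(D_gen[iu], D_lang[iu])[0, 1]
        assert res.r == pytest.approx(r_simple, abs=1e-10)

    def test_matches_vegan_statistic(self, tmp_path):
        # independent oracle: the partial Mantel statistic from R/vegan
        import shutil
        import subprocess

        rng = np.random.default_rng(10)
        D_gen, D_lang, D_geo = _mantel_world(rng, lang_effect=1.0)
        res = ms.partial_mantel(D_gen, D_lang, D_geo, n_perm=99, seed=0)
        for name, m in [("gen", D_gen), ("lang", D_lang), ("geo", D_geo)]:
            np.savetxt(tmp_path / f"{name}.tsv", m, delimiter="\t")
        script = tmp_path / "mantel.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'setwd("{tmp_path}")\n'
            'g <- as.dist(as.matrix(read.table("gen.tsv")))\n'
            'l <- as.dist(as.matrix(read.table("lang.tsv")))\n'
            'e <- as.dist(as.matrix(read.table("geo.tsv")))\n'
            'r <- mantel.partial(g, l, e, permutations = 9)\n'
            'cat(sprintf("%.12f", r$statistic))\n'
        )
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        out = subprocess.run([rscript, str(script)], capture_output=True,
                             text=True, check=True)
        r_vegan = float(out.stdout.strip())
        assert res.r == pytest.approx(r_vegan, abs=1e-6)


class TestLanguageDistance:
    def test_groups_and_nulls(self):
        labels = pd.Series(["KhoeSan", "KhoeSan", "Nilo-Saharan", None])
        D = ms.language_distance(labels)
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0
        assert np.isnan(D[0, 3])
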