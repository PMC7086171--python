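"""Surface model: tessellations, resistance distances, expected
dissimilarity, Wishart likelihood."""

import numpy as np
import pytest
from scipy.stats import gamma

import migscape as ms
from migscape.model import ExpectedDissimilarity, contrast_backproject, contrast_project

from conftest import random_connected_graph


def two_deme_delta(q, R12):
    between = np.array([
        [q[0], (q[0] + q[1]) / 2 + R12 / 4],
        [(q[0] + q[1]) / 2 + R12 / 4, q[1]],
    ])
    return ExpectedDissimilarity(np.array([0, 1]), between, np.asarray(q, float))


class TestTessellation:
    def test_single_tile_constant_surface(self, small_grid):
        tess = ms.RateTessellation(np.array([[200.0, 90.0]]), np.array([0.3]))
        rates = ms.rates_on_vertices(tess, small_grid)
        np.testing.assert_allclose(rates, 0.3)

    def test_two_tiles_split_by_side(self, small_grid):
        tess = ms.RateTessellation(np.array([[0.0, 90.0], [400.0, 90.0]]),
                                   np.array([-1.0, 1.0]))
        rates = ms.rates_on_vertices(tess, small_grid)
        left = small_grid.coords[:, 0] < 200
        assert np.all(rates[left] == -1.0)
        right = small_grid.coords[:, 0] > 200
        assert np.all(rates[right] == 1.0)

    def test_matches_brute_force_nearest_seed(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 50, size=(1000, 2))
        g = ms.DemeGraph(coords, [[0, 1]], 1.0)
        seeds = rng.uniform(0, 50, size=(17, 2))
        effects = rng.uniform(-2, 2, size=17)
        tess = ms.RateTessellation(seeds, effects, mean=0.4)
        rates = ms.rates_on_vertices(tess, g)
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        expected = 0.4 + effects[d.argmin(axis=1)]
        np.testing.assert_allclose(rates, expected)

    def test_effect_bound_enforced(self):
        with pytest.raises(ValueError):
            ms.RateTessellation(np.array([[0.0, 0.0]]), np.array([2.5]))

    @pytest.mark.parametrize("lm_u, lm_v, expected", [
        (0.0, 0.0, 1.0),
        (-1.0, 1.0, 1.0),
        (-2.0, 0.0, 0.1),
    ])
    def test_edge_conductance_geometric_mean(self, lm_u, lm_v, expected):
        g = ms.DemeGraph(np.array([[0.0, 0], [1, 0]]), [[0, 1]], 1.0)
        c = ms.rates_on_edges(np.array([lm_u, lm_v]), g)
        assert c[0] == pytest.approx(expected)


class TestResistance:
    def test_single_edge_is_ohm(self):
        g = ms.DemeGraph(np.array([[0.0, 0], [1, 0]]), [[0, 1]], 1.0)
        R = ms.resistance_distances(g, np.array([4.0]))
        assert R[0, 1] == pytest.approx(0.25)

    def test_unit_triangle(self):
        g = ms.DemeGraph(np.array([[0.0, 0], [1, 0], [0.5, 1]]),
                         [[0, 1], [1, 2], [0, 2]], 1.0)
        R = ms.resistance_distances(g, np.ones(3))
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(R[iu], 2 / 3)

    def test_matches_per_pair_linear_solve(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, n_max=20)
        c = rng.uniform(0.1, 5.0, size=g.n_edges)
        R = ms.resistance_distances(g, c)
        from migscape.model import graph_laplacian

        L = graph_laplacian(g, c)
        n = g.n_vertices
        worst = 0.0
        for u in range(n):
            for v in range(u + 1, n):
                b = np.zeros(n)
                b[u], b[v] = 1.0, -1.0
                # ground vertex v and solve the reduced system
                keep = np.arange(n) != v
                x = np.linalg.solve(L[np.ix_(keep, keep)], b[keep])
                worst = max(worst, abs(R[u, v] - x[u]))  # u < v, so index u survives
        assert worst < 1e-9

    def test_disconnected_graph_raises(self):
        g = ms.DemeGraph(np.array([[0.0, 0], [1, 0], [5, 5], [6, 5]]),
                         [[0, 1], [2, 3]], 1.0)
        with pytest.raises(ValueError):
            ms.resistance_distances(g, np.ones(2))

    def test_rayleigh_monotonicity(self):
        rng = np.random.default_rng(11)
        g = random_connected_graph(rng, n_max=15)
        c = rng.uniform(0.5, 2.0, size=g.n_edges)
        R = ms.resistance_distances(g, c)
        c2 = c.copy()
        c2[rng.integers(g.n_edges)] *= 0.5
        R2 = ms.resistance_distances(g, c2)
        assert np.all(R2 >= R - 1e-12)


class TestExpectedDissimilarity:
    def test_panmictic_limit(self, small_grid):
        R = np.zeros((small_grid.n_vertices,) * 2)
        q = np.full(small_grid.n_vertices, 0.7)
        delta = ms.expected_dissimilarity(R, q, np.arange(small_grid.n_vertices))
        np.testing.assert_allclose(delta.between, 0.7)

    def test_two_deme_arithmetic(self):
        R = np.array([[0.0, 1.0], [1.0, 0.0]])
        delta = ms.expected_dissimilarity(R, np.array([0.2, 0.4]), np.array([0, 1]))
        assert delta.between[0, 1] == pytest.approx(0.55)
        assert delta.between[0, 0] == pytest.approx(0.2)

    def test_conductance_scaling_scales_between_part(self, small_grid):
        rng = np.random.default_rng(0)
        lm = rng.normal(0, 0.5, small_grid.n_vertices)
        q = np.full(small_grid.n_vertices, 0.5)
        demes = np.arange(small_grid.n_vertices)
        c = ms.rates_on_edges(lm, small_grid)
        d1 = ms.expected_dissimilarity(
            ms.resistance_distances(small_grid, c), q, demes)
        d10 = ms.expected_dissimilarity(
            ms.resistance_distances(small_grid, 10 * c), q, demes)
        qbar = (q[:, None] + q[None, :]) / 2
        iu = np.triu_indices(len(demes), 1)
        np.testing.assert_allclose((d10.between - qbar)[iu],
                                   0.1 * (d1.between - qbar)[iu])

    def test_negative_q_raises(self, small_grid):
        R = np.zeros((small_grid.n_vertices,) * 2)
        with pytest.raises(ValueError):
            ms.expected_dissimilarity(R, np.full(small_grid.n_vertices, -0.1),
                                      np.arange(3))


class TestContrastBasis:
    def test_backproject_inverts_project(self):
        rng = np.random.default_rng(5)
        n = 9
        D = np.abs(rng.normal(size=(n, n)))
        D = D + D.T
        np.fill_diagonal(D, 0.0)
        B = -0.5 * contrast_project(D)
        np.testing.assert_allclose(contrast_backproject(B), D, atol=1e-12)


class TestWishartLoglik:
    def test_matches_1d_gamma_oracle(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            q = rng.uniform(0.2, 2.0, size=2)
            R12 = rng.uniform(0.1, 3.0)
            sigma2 = rng.uniform(0.3, 3.0)
            p = int(rng.integers(10, 500))
            delta = two_deme_delta(q, R12)
            d12 = rng.uniform(0.1, 4.0)
            D = np.array([[0.0, d12], [d12, 0.0]])
            ll = ms.wishart_loglik(D, delta, np.array([0, 1]), sigma2, p)
            M = delta.between[0, 1]  # scalar -1/2 C Delta* C^T
            ref = gamma.logpdf(d12 * p, a=p / 2, scale=2 * sigma2 * M)
            worst = max(worst, abs(ll - ref))
        assert worst < 1e-10

    def test_nonpositive_definite_flags_minus_inf(self):
        # force a negative within-deme term through the dataclass
        delta = two_deme_delta([0.5, 0.5], 1.0)
        delta.between = np.array([[0.5, -3.0], [-3.0, 0.5]])
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert ms.wishart_loglik(D, delta, np.array([0, 1]), 1.0, 10) == -np.inf

    def test_p_smaller_than_n_raises(self):
        delta = two_deme_delta([0.5, 0.5], 1.0)
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            ms.wishart_loglik(D, delta, np.array([0, 1]), 1.0, 1)

    def _random_problem(self, rng, n_demes=5, per_deme=3, p=200):
        coords = rng.uniform(0, 10, size=(n_demes, 2))
        edges = [[i, i + 1] for i in range(n_demes - 1)]
        g = ms.DemeGraph(coords, np.array(edges), 1.0)
        c = rng.uniform(0.5, 2.0, size=g.n_edges)
        R = ms.resistance_distances(g, c)
        q = rng.uniform(0.3, 1.0, size=n_demes)
        demes = np.arange(n_demes)
        delta = ms.expected_dissimilarity(R, q, demes)
        assign = np.repeat(demes, per_deme)
        dstar = ms.individual_expected_matrix(delta, assign)
        D = ms.simulate_model_exact(dstar, 1.3, p, seed=rng)
        return D, delta, assign, p

    def test_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(8)
        D, delta, assign, p = self._random_problem(rng)
        ll = ms.wishart_loglik(D, delta, assign, 1.3, p)
        perm = rng.permutation(len(assign))
        ll_perm = ms.wishart_loglik(D[np.ix_(perm, perm)], delta, assign[perm], 1.3, p)
        assert ll_perm == pytest.approx(ll, abs=1e-6)

    def test_scale_consistency_of_loglik_differences(self):
        # multiplying D by c and sigma2 by c leaves differences between
        # two candidate surfaces unchanged
        rng = np.random.default_rng(9)
        D, delta, assign, p = self._random_problem(rng)
        delta2 = ExpectedDissimilarity(delta.demes, delta.between * 1.5,
                                       delta.within * 1.5)
        diff1 = (ms.wishart_loglik(D, delta, assign, 1.0, p)
                 - ms.wishart_loglik(D, delta2, assign, 1.0, p))
        c = 3.7
        diff2 = (ms.wishart_loglik(c * D, delta, assign, c, p)
                 - ms.wishart_loglik(c * D, delta2, assign, c, p))
        assert diff2 == pytest.approx(diff1, rel=1e-9)

    def test_likelihood_consistency_truth_beats_perturbation(self, small_grid):
        # mean loglik at the generating surface >= mean loglik with
        # conductances perturbed x3, over model-exact replicates
        rng = np.random.default_rng(10)
        g = small_grid
        demes = np.arange(g.n_vertices)
        q = np.full(g.n_vertices, 0.6)
        c0 = ms.rates_on_edges(np.zeros(g.n_vertices), g)
        delta0 = ms.expected_dissimilarity(
            ms.resistance_distances(g, c0), q, demes)
        lm_pert = np.where(g.coords[:, 0] < 200, np.log10(3.0), 0.0)
        delta_pert = ms.expected_dissimilarity(
            ms.resistance_distances(g, ms.rates_on_edges(lm_pert, g)), q, demes)
        assign = np.repeat(demes, 2)
        dstar = ms.individual_expected_matrix(delta0, assign)
        p = 200
        diffs = []
        for _ in range(50):
            D = ms.simulate_model_exact(dstar, 1.0, p, seed=rng)
            diffs.append(ms.wishart_loglik(D, delta0, assign, 1.0, p)
                         - ms.wishart_loglik(D, delta_pert, assign, 1.0, p))
        assert np.mean(diffs) > 0
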