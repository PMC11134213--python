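import numpy as np
import pytest

from metadyad.pls import (
    Q2_LIMIT,
    center_scale,
    fit_canonical_pls,
    permutation_test_covariance,
    relevance_network,
    residualize,
    select_components_q2,
    soft_threshold_keep,
    tune_sparsity,
    variance_explained,
)


def _planted_blocks(rng, n=60, p=12, q=9, strength=1.0, noise=0.5):
    f = rng.standard_normal(n)
    lx = rng.standard_normal(p)
    ly = rng.standard_normal(q)
    X = strength * np.outer(f, lx) + noise * rng.standard_normal((n, p))
    Y = strength * np.outer(f, ly) + noise * rng.standard_normal((n, q))
    return center_scale(X), center_scale(Y)


class TestPreprocessing:
    def test_residualize_orthogonal_column_unchanged(self, rng):
        n = 50
        c = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), c])
        m = rng.standard_normal(n)
        # project out the covariate space first, then residualize again
        m_orth = m - design @ np.linalg.lstsq(design, m, rcond=None)[0]
        out = residualize(m_orth[:, None], design)
        np.testing.assert_allclose(out[:, 0], m_orth, atol=1e-12)

    def test_residualize_covariate_column_zeroed(self, rng):
        n = 40
        c = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), c])
        out = residualize(c[:, None], design)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_every_covariate(self, rng):
        n = 45
        design = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        M = rng.standard_normal((n, 6))
        out = residualize(M, design)
        np.testing.assert_allclose(design.T @ out, 0.0, atol=1e-9)

    def test_residualize_rank_deficient_rejected(self, rng):
        n = 30
        c = rng.standard_normal(n)
        design = np.column_stack([np.ones(n), c, 2 * c])
        with pytest.raises(np.linalg.LinAlgError):
            residualize(rng.standard_normal((n, 2)), design)

    def test_center_scale_means_and_variances(self, rng):
        M = rng.lognormal(size=(30, 5))
        out = center_scale(M)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_center_scale_idempotent_on_standardized(self, rng):
        M = center_scale(rng.standard_normal((25, 4)))
        np.testing.assert_allclose(center_scale(M), M, atol=1e-12)

    def test_center_scale_constant_column_rejected(self, rng):
        M = np.column_stack([np.ones(20), rng.standard_normal(20)])
        with pytest.raises(ValueError, match="constant"):
            center_scale(M)


class TestSoftThreshold:
    def test_keeps_k_largest_and_shrinks(self):
        v = np.array([3.0, -1.0, 0.5, -4.0])
        out = soft_threshold_keep(v, 2)
        np.testing.assert_allclose(out, [2.0, 0.0, 0.0, -3.0])

    def test_full_budget_identity(self, rng):
        v = rng.standard_normal(7)
        np.testing.assert_allclose(soft_threshold_keep(v, 7), v)

    def test_all_zero_result_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            soft_threshold_keep(np.array([1.0, 1.0, 1.0]), 2)


class TestCanonicalPLS:
    def test_dense_first_pair_matches_svd_oracle(self, rng):
        for _ in range(5):
            X = center_scale(rng.standard_normal((30, 10)))
            Y = center_scale(rng.standard_normal((30, 8)))
            fit = fit_canonical_pls(X, Y, 1)
            U, _, Vt = np.linalg.svd(X.T @ Y)
            a, b = U[:, 0], Vt[0]
            if a[np.argmax(np.abs(a))] < 0:
                a, b = -a, -b
            np.testing.assert_allclose(fit.loadings_x[:, 0], a, atol=1e-8)
            np.testing.assert_allclose(fit.loadings_y[:, 0], b, atol=1e-8)

    def test_first_component_maximizes_covariance_exhaustive(self, rng):
        # toy 2-3 column blocks: compare with a dense grid over unit vectors
        X = center_scale(rng.standard_normal((40, 2)))
        Y = center_scale(rng.standard_normal((40, 3)))
        fit = fit_canonical_pls(X, Y, 1)
        th = np.linspace(0, np.pi, 721)
        A = np.column_stack([np.cos(th), np.sin(th)])  # all unit a
        phi, psi = np.meshgrid(
            np.linspace(0, np.pi, 181), np.linspace(0, 2 * np.pi, 361)
        )
        B = np.column_stack(
            [
                (np.sin(phi) * np.cos(psi)).ravel(),
                (np.sin(phi) * np.sin(psi)).ravel(),
                np.cos(phi).ravel(),
            ]
        )  # all unit b
        covs = np.abs((X @ A.T).T @ (Y @ B.T)) / (len(X) - 1)
        assert fit.covariances[0] >= covs.max() - 1e-3

    def test_identical_blocks_give_identical_loadings_and_perfect_corr(self, rng):
        X = center_scale(rng.standard_normal((25, 6)))
        fit = fit_canonical_pls(X, X.copy(), 1)
        np.testing.assert_allclose(fit.loadings_x, fit.loadings_y, atol=1e-8)
        corr = np.corrcoef(fit.scores_x[:, 0], fit.scores_y[:, 0])[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_keep_one_gives_single_nonzero_loading(self, rng):
        X = center_scale(rng.standard_normal((30, 9)))
        Y = center_scale(rng.standard_normal((30, 7)))
        fit = fit_canonical_pls(X, Y, 1, keep_x=(1,), keep_y=(7,))
        assert np.count_nonzero(fit.loadings_x[:, 0]) == 1

    def test_sparse_with_full_budgets_equals_dense(self, rng):
        X = center_scale(rng.standard_normal((30, 10)))
        Y = center_scale(rng.standard_normal((30, 8)))
        dense = fit_canonical_pls(X, Y, 3)
        sparse = fit_canonical_pls(X, Y, 3, keep_x=(10,) * 3, keep_y=(8,) * 3)
        np.testing.assert_array_equal(sparse.loadings_x, dense.loadings_x)
        np.testing.assert_array_equal(sparse.scores_y, dense.scores_y)

    def test_scores_orthogonal_within_block(self, rng):
        X, Y = _planted_blocks(rng)
        fit = fit_canonical_pls(X, Y, 3)
        G = fit.scores_x.T @ fit.scores_x
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        G = fit.scores_y.T @ fit.scores_y
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_unit_norm_loadings_and_sign_convention(self, rng):
        X, Y = _planted_blocks(rng)
        fit = fit_canonical_pls(X, Y, 2)
        np.testing.assert_allclose(np.linalg.norm(fit.loadings_x, axis=0), 1.0)
        np.testing.assert_allclose(np.linalg.norm(fit.loadings_y, axis=0), 1.0)
        for h in range(2):
            a = fit.loadings_x[:, h]
            assert a[np.argmax(np.abs(a))] > 0


class TestVarianceExplained:
    def test_rank_one_shared_blocks_first_pair_is_one(self, rng):
        f = rng.standard_normal(40)
        X = np.outer(f, rng.standard_normal(6))
        Y = np.outer(f, rng.standard_normal(5))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        fit = fit_canonical_pls(X, Y, 1)
        ve = variance_explained(fit, X, Y)
        assert ve["pair"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_proportions_sum_below_one_random_blocks(self, rng):
        X, Y = _planted_blocks(rng, noise=1.5)
        fit = fit_canonical_pls(X, Y, 3)
        ve = variance_explained(fit, X, Y)
        assert ve["x"].iloc[0] < 1.0
        assert ve["x"].sum() <= 1.0 + 1e-12
        assert ve["y"].sum() <= 1.0 + 1e-12


class TestQ2Selection:
    def test_planted_factor_retains_at_least_one(self, rng):
        X, Y = _planted_blocks(rng, strength=1.5, noise=0.5)
        retained, table = select_components_q2(X, Y, 2)
        assert retained >= 1
        assert table["q2"].iloc[0] >= Q2_LIMIT

    def test_pure_noise_retains_zero_mostly(self, rng):
        zeros = 0
        for _ in range(10):
            X = center_scale(rng.standard_normal((50, 10)))
            Y = center_scale(rng.standard_normal((50, 8)))
            retained, _ = select_components_q2(X, Y, 1)
            zeros += retained == 0
        assert zeros >= 9

    def test_q2_never_exceeds_one(self, rng):
        X, Y = _planted_blocks(rng)
        _, table = select_components_q2(X, Y, 3)
        assert (table["q2"] <= 1.0 + 1e-12).all()

    def test_too_small_n_rejected(self, rng):
        X = center_scale(rng.standard_normal((8, 4)))
        with pytest.raises(ValueError, match="at least 10"):
            select_components_q2(X, X.copy(), 1)

    def test_tune_sparsity_returns_grid_values(self, rng):
        X, Y = _planted_blocks(rng, n=40, p=12, q=9)
        kx, ky = tune_sparsity(X, Y)
        assert kx in {5, 10, 12}
        assert ky in {5, 9}


class TestPermutationTest:
    def test_p_floor_when_observed_exceeds_all(self, rng):
        X, Y = _planted_blocks(rng, strength=2.0, noise=0.3)
        res = permutation_test_covariance(X, Y, B=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.count_ge == 0

    def test_seed_reproducible(self, rng):
        X = center_scale(rng.standard_normal((30, 6)))
        Y = center_scale(rng.standard_normal((30, 5)))
        r1 = permutation_test_covariance(X, Y, B=99, seed=7)
        r2 = permutation_test_covariance(X, Y, B=99, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.count_ge == r2.count_ge

    def test_null_p_values_super_uniform(self, rng):
        # small replicate check; the full calibration lives in acceptance
        pvals = [
            permutation_test_covariance(
                center_scale(rng.standard_normal((40, 6))),
                center_scale(rng.standard_normal((40, 5))),
                B=99,
                seed=s,
            ).p_value
            for s in range(30)
        ]
        assert min(pvals) >= 1 / 100
        assert np.mean(np.array(pvals) <= 0.2) <= 0.45

    def test_invalid_b_rejected(self, rng):
        X = center_scale(rng.standard_normal((20, 3)))
        with pytest.raises(ValueError):
            permutation_test_covariance(X, X.copy(), B=0)


class TestRelevanceNetwork:
    def test_threshold_validation_and_empty_at_one(self, rng):
        X, Y = _planted_blocks(rng, noise=2.0)
        fit = fit_canonical_pls(X, Y, 1)
        with pytest.raises(ValueError):
            relevance_network(fit, X, Y, threshold=1.5)
        net = relevance_network(fit, X, Y, threshold=1.0)
        assert net.graph.number_of_edges() == 0

    def test_planted_identical_variable_strong_positive_edge(self, rng):
        n = 80
        f = rng.standard_normal(n)
        v = f + 0.1 * rng.standard_normal(n)  # same variable in both blocks
        X = np.column_stack([v, f + 0.6 * rng.standard_normal((n, 4)).T[0],
                             0.8 * rng.standard_normal(n)])
        Y = np.column_stack([v, f + 0.6 * rng.standard_normal(n)])
        Xs, Ys = center_scale(X), center_scale(Y)
        fit = fit_canonical_pls(Xs, Ys, 1)
        net = relevance_network(
            fit, Xs, Ys, threshold=0.5, x_names=["shared", "x1", "x2"],
            y_names=["shared", "y1"], x_block="placenta", y_block="cord_serum",
        )
        edge = net.graph.get_edge_data("placenta:shared", "cord_serum:shared")
        assert edge is not None
        assert edge["sign"] == 1

    def test_similarity_bounded_single_component(self, rng):
        X, Y = _planted_blocks(rng)
        fit = fit_canonical_pls(X, Y, 1)
        net = relevance_network(fit, X, Y, threshold=0.0)
        assert net.similarity.abs().to_numpy().max() <= 1.0 + 1e-12

    def test_edges_connect_blocks_only_and_tsv_export(self, rng, tmp_path):
        X, Y = _planted_blocks(rng, strength=2.0, noise=0.4)
        fit = fit_canonical_pls(X, Y, 1)
        net = relevance_network(fit, X, Y, threshold=0.5, x_block="placenta",
                                y_block="cord_serum")
        assert net.graph.number_of_edges() > 0
        for a, b in net.graph.edges():
            assert net.graph.nodes[a]["block"] != net.graph.nodes[b]["block"]
        out = tmp_path / "edges.tsv"
        net.write_edge_tsv(out)
        assert out.read_text().startswith("node_x\tnode_y\tsimilarity\tsign")
        net.write_graphml(tmp_path / "net.graphml")
        assert (tmp_path / "net.graphml").stat().st_size > 0
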