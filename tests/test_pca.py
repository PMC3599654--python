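import numpy as np
import pytest

from mwaspca import (
    CovariateTable,
    decompose,
    dominant_components,
    prepare,
    residualize,
    run_pca,
    scree,
    similarity_chunked,
)
from mwaspca.pca import assemble_similarity, compute_chunk_pair

from conftest import as_methylation


def direct_covariance_pca(X: np.ndarray):
    """Oracle: eigen-decompose the p x p covariance matrix directly."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    w, V = w[::-1], V[:, ::-1]
    keep = w > 1e-9 * max(w[0], 0)
    return w[keep], V[:, keep], Xc @ V[:, keep]


def pca_of(X, mode="covariance", **kwargs):
    data = as_methylation(np.asarray(X, dtype=float))
    prep = prepare(data, mode)
    M = similarity_chunked(prep, chunk_size=prep.n)
    kwargs.setdefault("n_components", min(prep.n, prep.p))
    kwargs.setdefault("n_loadings", kwargs["n_components"])
    return decompose(M, prep=prep, **kwargs), prep


class TestResidualize:
    def covs(self, values, names=None):
        n = len(values)
        names = names or [f"c{i}" for i in range(np.atleast_2d(np.asarray(values).T).shape[0])]
        return CovariateTable([f"s{i}" for i in range(n)], names, np.reshape(values, (n, -1)))

    def test_perfect_covariate_leaves_zero_residual(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(30)
        data = as_methylation(col[:, None])
        out = residualize(data, self.covs(col, ["c0"]), ["c0"])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_independent_covariate_keeps_centered_data(self):
        rng = np.random.default_rng(1)
        n = 1000
        data = as_methylation(rng.standard_normal((n, 3)) + 5.0)
        out = residualize(data, self.covs(rng.standard_normal(n), ["c0"]), ["c0"])
        centered = data.values - data.values.mean(axis=0)
        for j in range(3):
            r = np.corrcoef(out.values[:, j], centered[:, j])[0, 1]
            assert r > 0.99

    def test_matches_closed_form_normal_equations(self):
        # 5-subject example solved by hand: y = 2 c + e, regress y on [1, c]
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([0.5, -0.3, 0.1, -0.4, 0.2])
        y = 2.0 * c + e
        D = np.column_stack([np.ones(5), c])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        expected = y - D @ beta
        out = residualize(as_methylation(y[:, None]), self.covs(c, ["c0"]), ["c0"])
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        n = 50
        Z = rng.standard_normal((n, 2))
        data = as_methylation(rng.standard_normal((n, 8)) + Z @ rng.standard_normal((2, 8)))
        covs = CovariateTable([f"s{i}" for i in range(n)], ["a", "b"], Z)
        out = residualize(data, covs, ["a", "b"])
        dots = np.abs(Z.T @ out.values)
        norms = np.linalg.norm(Z, axis=0)[:, None] * np.linalg.norm(out.values, axis=0)
        assert np.all(dots <= 1e-8 * norms)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        n = 40
        covs = CovariateTable([f"s{i}" for i in range(n)], ["a"], rng.standard_normal((n, 1)))
        data = as_methylation(rng.standard_normal((n, 5)))
        once = residualize(data, covs, ["a"])
        twice = residualize(once, covs, ["a"])
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        n = 20
        z = rng.standard_normal(n)
        covs = CovariateTable([f"s{i}" for i in range(n)], ["a", "b"], np.column_stack([z, 2 * z]))
        data = as_methylation(rng.standard_normal((n, 3)))
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(data, covs, ["a", "b"])


class TestPrepare:
    def test_covariance_centering(self):
        data = as_methylation(np.array([[0.0, 0.0], [2.0, 4.0]]))
        prep = prepare(data, "covariance")
        np.testing.assert_allclose(prep.X, [[-1.0, -2.0], [1.0, 2.0]])

    def test_constant_matrix_covariance_gives_zeros(self):
        prep = prepare(as_methylation(np.full((4, 3), 5.0)), "covariance")
        np.testing.assert_allclose(prep.X, 0.0)

    def test_correlation_unit_variance(self):
        data = as_methylation(np.array([[0.0, 0.0], [2.0, 4.0]]))
        prep = prepare(data, "correlation")
        np.testing.assert_allclose(prep.X.var(axis=0, ddof=1), 1.0)

    def test_correlation_drops_constant_columns_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            prep = prepare(as_methylation(X), "correlation")
        assert prep.p == 1
        assert list(prep.dropped) == [1]

    def test_all_constant_correlation_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            prepare(as_methylation(np.full((4, 2), 1.0)), "correlation")

    def test_column_means_zero_to_tolerance(self):
        rng = np.random.default_rng(5)
        prep = prepare(as_methylation(rng.gamma(2, 10, size=(20, 30))), "covariance")
        scale = np.abs(prep.col_means)
        assert np.all(np.abs(prep.X.mean(axis=0)) <= 1e-10 * np.maximum(scale, 1))


class TestChunking:
    def test_tiny_matrix_all_chunk_sizes_agree(self):
        X = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        prep = prepare(as_methylation(X), "covariance")
        Ms = [similarity_chunked(prep, cs).M for cs in (1, 2, 3)]
        np.testing.assert_allclose(Ms[0], Ms[2], atol=1e-12)
        np.testing.assert_allclose(Ms[1], Ms[2], atol=1e-12)

    def test_random_matrix_chunked_vs_direct(self):
        rng = np.random.default_rng(6)
        prep = prepare(as_methylation(rng.standard_normal((50, 2000))), "covariance")
        direct = prep.X @ prep.X.T / 49  # independent single-product oracle
        for cs in (1, 7, 50):
            M = similarity_chunked(prep, cs).M
            assert np.abs(M - direct).max() <= 1e-10

    def test_duplicated_subject_rows_mirror_in_M(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((6, 40))
        X[3] = X[1]
        prep = prepare(as_methylation(X), "covariance")
        M = similarity_chunked(prep, 2).M
        np.testing.assert_allclose(M[1], M[3], atol=1e-12)
        np.testing.assert_allclose(M[:, 1], M[:, 3], atol=1e-12)

    def test_scratch_dir_persistence_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        prep = prepare(as_methylation(rng.standard_normal((10, 30))), "covariance")
        M_mem = similarity_chunked(prep, 4).M
        M_disk = similarity_chunked(prep, 4, scratch_dir=tmp_path / "scratch").M
        np.testing.assert_allclose(M_disk, M_mem, atol=1e-12)
        # out-of-order assembly from the persisted products gives the same M
        M_re = assemble_similarity(10, 4, tmp_path / "scratch").M
        np.testing.assert_allclose(M_re, M_mem, atol=1e-12)

    def test_chunk_pair_jobs_cover_product(self):
        rng = np.random.default_rng(9)
        prep = prepare(as_methylation(rng.standard_normal((7, 20))), "covariance")
        P = compute_chunk_pair(prep, 3, 0, 2)
        np.testing.assert_allclose(P, prep.X[0:3] @ prep.X[6:7].T)

    def test_invalid_chunk_size(self):
        rng = np.random.default_rng(10)
        prep = prepare(as_methylation(rng.standard_normal((5, 4))), "covariance")
        with pytest.raises(ValueError, match="chunk_size"):
            similarity_chunked(prep, 0)


class TestDecompose:
    def test_rank_one_single_column(self):
        rng = np.random.default_rng(11)
        col = rng.standard_normal(12)
        X = np.zeros((12, 4))
        X[:, 2] = col
        with pytest.warns(UserWarning, match="numerical rank"):
            result, _ = pca_of(X, n_components=4, n_loadings=4)
        c = col - col.mean()
        assert result.eigenvalues.size == 1
        assert result.eigenvalues[0] == pytest.approx(c.var(ddof=1))
        # PC1 = +-centered column; loading is the unit vector on column 2
        sign = np.sign(result.scores[np.abs(c).argmax(), 0] * c[np.abs(c).argmax()])
        np.testing.assert_allclose(result.scores[:, 0] * sign, c, atol=1e-8)
        np.testing.assert_allclose(np.abs(result.loadings[:, 0]), [0, 0, 1, 0], atol=1e-8)

    def test_matches_direct_covariance_pca(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((10, 50))
        result, prep = pca_of(X, n_components=9, n_loadings=9)
        w, V, scores = direct_covariance_pca(X)
        np.testing.assert_allclose(result.eigenvalues, w, rtol=1e-8)
        for i in range(9):
            dot = result.scores[:, i] @ scores[:, i]
            np.testing.assert_allclose(
                result.scores[:, i], np.sign(dot) * scores[:, i], atol=1e-8
            )
            dot_v = result.loadings[:, i] @ V[:, i]
            np.testing.assert_allclose(
                result.loadings[:, i], np.sign(dot_v) * V[:, i], atol=1e-8
            )

    def test_scores_are_data_times_loadings(self):
        rng = np.random.default_rng(13)
        result, prep = pca_of(rng.standard_normal((10, 50)), n_components=9, n_loadings=9)
        np.testing.assert_allclose(prep.X @ result.loadings, result.scores, atol=1e-8)

    def test_result_invariants(self):
        rng = np.random.default_rng(14)
        result, prep = pca_of(rng.standard_normal((15, 80)), n_components=10, n_loadings=5)
        ev = result.eigenvalues
        assert np.all(np.diff(ev) <= 0)
        G = result.eigenvectors.T @ result.eigenvectors
        np.testing.assert_allclose(G, np.eye(ev.size), atol=1e-8)
        np.testing.assert_allclose(
            result.scores.var(axis=0, ddof=1), ev[:10], rtol=1e-6
        )
        np.testing.assert_allclose(np.linalg.norm(result.loadings, axis=0), 1.0, rtol=1e-6)
        # variance decomposition: sum of eigenvalues = total column variance
        np.testing.assert_allclose(
            ev.sum(), prep.X.var(axis=0, ddof=1).sum(), rtol=1e-6
        )

    def test_correlation_mode_equals_covariance_of_standardized(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((12, 40)) * rng.uniform(0.5, 20, size=40)
        res_corr, _ = pca_of(X, mode="correlation", n_components=11, n_loadings=0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        res_cov, _ = pca_of(Xs, mode="covariance", n_components=11, n_loadings=0)
        np.testing.assert_allclose(res_corr.eigenvalues, res_cov.eigenvalues, rtol=1e-8)
        np.testing.assert_allclose(res_corr.scores, res_cov.scores, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((10, 30))
        r1, _ = pca_of(X.copy(), n_components=5, n_loadings=0)
        r2, _ = pca_of(X.copy(), n_components=5, n_loadings=0)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        idx = np.abs(r1.eigenvectors).argmax(axis=0)
        assert np.all(r1.eigenvectors[idx, np.arange(idx.size)] > 0)

    def test_scores_only_when_no_loadings_requested(self):
        rng = np.random.default_rng(17)
        result, _ = pca_of(rng.standard_normal((8, 20)), n_components=3, n_loadings=0)
        assert result.loadings.shape == (20, 0)


class TestScree:
    def test_top_one_is_largest(self):
        rng = np.random.default_rng(18)
        result, _ = pca_of(rng.standard_normal((10, 30)))
        assert scree(result, 1)[0] == result.eigenvalues.max()

    def test_pure_noise_has_no_dominant_gap(self):
        rng = np.random.default_rng(19)
        result, _ = pca_of(rng.standard_normal((500, 5000)), n_components=10, n_loadings=0)
        ev = scree(result, 10)
        assert ev[0] / ev[9] < 3

    def test_planted_factors_recovered(self):
        # 5 shared factors on 600 x 400 data -> a clear gap after component 5
        rng = np.random.default_rng(20)
        F = rng.standard_normal((600, 5))
        L = rng.standard_normal((5, 400)) * 2.0
        X = F @ L + rng.standard_normal((600, 400))
        result, _ = pca_of(X, n_components=10, n_loadings=0)
        ev = scree(result, 10)
        assert ev[4] / ev[5] > 2
        assert dominant_components(ev, 10) == 5


class TestRunPca:
    def test_front_end_equals_manual_path(self):
        rng = np.random.default_rng(21)
        data = as_methylation(rng.standard_normal((20, 60)))
        manual, _ = pca_of(data.values, n_components=5, n_loadings=2)
        front = run_pca(data, n_components=5, n_loadings=2, chunk_size=7)
        np.testing.assert_allclose(front.scores, manual.scores, atol=1e-9)
        np.testing.assert_allclose(front.loadings, manual.loadings, atol=1e-9)
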