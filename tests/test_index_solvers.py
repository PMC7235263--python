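"""Unit and property tests for the selection-index solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from regsi.index_solvers import (
    CovariancePair,
    compute_index,
    default_lambda_grid,
    elastic_net_psi,
    kkt_violation,
    l2_psi,
    lars_psi,
    pc_si,
    phenotypic_covariance,
    spectral_decomposition,
    standard_si,
)

from conftest import random_cov


def qp_solve(cov: CovariancePair, lam: float, alpha: float) -> np.ndarray:
    """Brute-force oracle: solve the elastic-net objective as a smooth QP in
    the positive/negative split parameterization (beta = u - v, u, v >= 0)."""
    p = cov.p

    def obj(z):
        u, v = z[:p], z[p:]
        beta = u - v
        return (-cov.G @ beta + 0.5 * beta @ cov.P @ beta
                + 0.5 * lam * (1 - alpha) * beta @ beta
                + lam * alpha * np.sum(u + v))

    res = minimize(obj, np.zeros(2 * p), method="SLSQP",
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x[:p] - res.x[p:]


class TestPhenotypicCovariance:
    def test_orthonormal_columns_give_identity(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((20, 4))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(19)
        X -= X.mean(axis=0)  # re-center after scaling
        P = phenotypic_covariance(X)
        # qr columns are orthonormal but not exactly mean-centered; compare
        # against the direct two-pass covariance instead of strict identity
        assert np.allclose(P, np.cov(X.T), atol=1e-12)

    def test_duplicate_columns_block(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])
        X -= X.mean(axis=0)
        P = phenotypic_covariance(X)
        assert P[0, 0] == pytest.approx(P[0, 1], abs=1e-12)
        assert P[0, 0] == pytest.approx(P[1, 1], abs=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 5))
        X -= X.mean(axis=0)
        P = phenotypic_covariance(X)
        n = 100
        for i in range(5):
            for j in range(5):
                cij = np.sum((X[:, i] - X[:, i].mean())
                             * (X[:, j] - X[:, j].mean())) / (n - 1)
                assert P[i, j] == pytest.approx(cij, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 rows"):
            phenotypic_covariance(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="centered"):
            phenotypic_covariance(np.ones((10, 2)))


class TestStandardSI:
    def test_hand_example(self, two_band_cov):
        beta = standard_si(two_band_cov).beta
        assert beta == pytest.approx([0.26667, 0.06667], abs=1e-3)

    def test_identity_covariance(self):
        g = np.array([0.4, -0.2, 0.1])
        cov = CovariancePair(np.eye(3), g, 1.0)
        assert np.allclose(standard_si(cov).beta, g)

    def test_zero_genetic_covariance(self):
        cov = CovariancePair(np.eye(3), np.zeros(3), 1.0)
        coef = standard_si(cov)
        assert np.all(coef.beta == 0)
        assert coef.n_active == 0

    def test_singular_matrix_advises_regularization(self):
        P = np.ones((3, 3)) + 1e-14 * np.eye(3)
        cov = CovariancePair(0.5 * (P + P.T), np.array([0.1, 0.2, 0.3]), 1.0)
        with pytest.raises(np.linalg.LinAlgError, match="regularized"):
            standard_si(cov)


class TestL2PSI:
    def test_hand_example(self, two_band_cov):
        beta = l2_psi(two_band_cov, 0.5).beta
        assert beta == pytest.approx([0.175, 0.075], abs=1e-6)

    def test_lambda_zero_reduces_to_standard(self, two_band_cov):
        assert np.allclose(l2_psi(two_band_cov, 0.0).beta,
                           standard_si(two_band_cov).beta, atol=1e-10)

    def test_huge_lambda_shrinks_to_zero(self, two_band_cov):
        beta = l2_psi(two_band_cov, 1e6).beta
        assert np.max(np.abs(beta)) < 1e-5 * np.max(np.abs(two_band_cov.G))

    def test_negative_lambda_rejected(self, two_band_cov):
        with pytest.raises(ValueError, match="lambda"):
            l2_psi(two_band_cov, -0.1)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(3)
        cov = random_cov(rng, 8)
        lams = np.geomspace(1e-3, 10.0, 50)
        norms = [np.linalg.norm(l2_psi(cov, lam).beta) for lam in lams]
        assert np.all(np.diff(norms) <= 1e-12)


class TestElasticNet:
    def test_hand_example_single_active_regime(self, two_band_cov):
        path = elastic_net_psi(two_band_cov, lambda_grid=[0.2], alpha=1.0)
        assert path.coefficients[0].beta == pytest.approx([0.1, 0.0], abs=1e-6)

    def test_lambda_max_gives_null_solution(self, two_band_cov):
        path = elastic_net_psi(two_band_cov, lambda_grid=[0.35, 0.3], alpha=1.0)
        assert np.all(path.coefficients[0].beta == 0)
        assert np.all(path.coefficients[1].beta == 0)

    def test_alpha_zero_matches_ridge(self, two_band_cov):
        path = elastic_net_psi(two_band_cov, lambda_grid=[0.5, 0.1], alpha=0.0)
        for c in path.coefficients:
            assert np.allclose(c.beta, l2_psi(two_band_cov, c.lam).beta,
                               atol=1e-8)

    def test_alpha_out_of_range(self, two_band_cov):
        with pytest.raises(ValueError, match="alpha"):
            elastic_net_psi(two_band_cov, lambda_grid=[0.1], alpha=1.2)

    def test_increasing_grid_rejected(self, two_band_cov):
        with pytest.raises(ValueError, match="decreasing"):
            elastic_net_psi(two_band_cov, lambda_grid=[0.1, 0.2], alpha=1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.integers(2, 8),
           alpha=st.floats(0.1, 1.0))
    def test_kkt_certificate_random_instances(self, seed, p, alpha):
        """The KKT conditions certify every coordinate-descent solution."""
        rng = np.random.default_rng(seed)
        cov = random_cov(rng, p)
        grid = default_lambda_grid(cov, alpha, n_points=8)
        path = elastic_net_psi(cov, lambda_grid=grid, alpha=alpha)
        for c in path.coefficients:
            assert kkt_violation(cov, c.beta, c.lam, alpha) < 1e-6

    def test_warm_vs_cold_start_agree(self):
        rng = np.random.default_rng(7)
        cov = random_cov(rng, 10)
        grid = default_lambda_grid(cov, 1.0, n_points=12)
        warm = elastic_net_psi(cov, lambda_grid=grid, alpha=1.0)
        for lam, c in zip(grid, warm.coefficients):
            cold = elastic_net_psi(cov, lambda_grid=[lam], alpha=1.0)
            assert np.allclose(c.beta, cold.coefficients[0].beta, atol=1e-6)

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(11)
        cov = random_cov(rng, 5)
        for alpha in (1.0, 0.5):
            grid = default_lambda_grid(cov, alpha, n_points=5)
            path = elastic_net_psi(cov, lambda_grid=grid, alpha=alpha)
            for c in path.coefficients:
                ref = qp_solve(cov, c.lam, alpha)
                assert np.allclose(c.beta, ref, atol=1e-5)


class TestLARS:
    def test_hand_knots(self, two_band_cov):
        path = lars_psi(two_band_cov)
        assert path.lambdas[0] == pytest.approx(0.3, abs=1e-8)
        assert path.lambdas[1] == pytest.approx(0.1, abs=1e-8)
        assert path.at(0.2).beta == pytest.approx([0.1, 0.0], abs=1e-8)

    def test_zero_g_single_null_solution(self):
        cov = CovariancePair(np.eye(3), np.zeros(3), 1.0)
        path = lars_psi(cov)
        assert len(path) == 1
        assert np.all(path.coefficients[0].beta == 0)

    def test_null_region_is_lambda_max_and_above(self):
        rng = np.random.default_rng(4)
        cov = random_cov(rng, 6)
        lam_max = np.max(np.abs(cov.G))
        path = lars_psi(cov)
        assert path.lambdas[0] == pytest.approx(lam_max, abs=1e-12)
        assert np.all(path.at(lam_max * 1.01).beta == 0)
        assert np.any(path.at(lam_max * 0.99).beta != 0)

    def test_kkt_at_every_knot(self):
        rng = np.random.default_rng(5)
        cov = random_cov(rng, 12)
        path = lars_psi(cov)
        for lam, c in zip(path.lambdas, path.coefficients):
            assert kkt_violation(cov, c.beta, lam, 1.0) < 1e-8

    def test_matches_coordinate_descent(self):
        rng = np.random.default_rng(6)
        cov = random_cov(rng, 10)
        lams = default_lambda_grid(cov, 1.0, n_points=20)
        lams = lams[lams < np.max(np.abs(cov.G))]
        path = lars_psi(cov)
        cd = elastic_net_psi(cov, lambda_grid=lams, alpha=1.0)
        for lam, c in zip(lams, cd.coefficients):
            assert np.allclose(path.at(lam).beta, c.beta, atol=1e-5)

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(8)
        cov = random_cov(rng, 10)
        path = lars_psi(cov)
        for lam in np.geomspace(np.max(np.abs(cov.G)) * 0.95, 1e-3, 20):
            ref = qp_solve(cov, lam, 1.0)
            assert np.allclose(path.at(lam).beta, ref, atol=1e-5)

    def test_matches_sklearn_gram_path(self):
        """Cross-check against an independent LARS implementation fed the
        same covariance inputs."""
        sklm = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(9)
        n, p = 200, 7
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        y -= y.mean()
        P = X.T @ X / n
        G = X.T @ y / n
        cov = CovariancePair(P, G, 1.0)
        path = lars_psi(cov)
        alphas, _, coefs = sklm.lars_path(
            X, y, Gram=P * n, Xy=G * n, method="lasso")
        for lam, ref in zip(alphas, coefs.T):
            assert np.allclose(path.at(lam).beta, ref, atol=1e-6)


class TestPCSI:
    @staticmethod
    def make_X(rng, n=40, p=6, rank=None):
        X = rng.standard_normal((n, rank or p))
        if rank:
            X = X @ rng.standard_normal((rank, p))
        X -= X.mean(axis=0)
        return X

    def test_full_rank_reduces_to_standard(self):
        rng = np.random.default_rng(10)
        X = self.make_X(rng)
        dec = spectral_decomposition(X, center=False)
        G = 0.2 * rng.standard_normal(6)
        cov = CovariancePair(phenotypic_covariance(X), G, 1.0)
        beta_pc = pc_si(dec, dec.V.T @ G, 6).beta
        assert np.allclose(beta_pc, standard_si(cov).beta, atol=1e-8)

    def test_single_component_formula(self):
        rng = np.random.default_rng(12)
        X = self.make_X(rng)
        dec = spectral_decomposition(X, center=False)
        G_wy = 0.1 * rng.standard_normal(6)
        beta = pc_si(dec, G_wy, 1).beta
        expected = dec.V[:, 0] * (dec.n - 1) * G_wy[0] / dec.D[0] ** 2
        assert np.allclose(beta, expected, atol=1e-12)

    def test_exact_rank_matches_score_regression(self):
        """On an exact rank-3 matrix, the q=3 index values match a direct
        regression on the scores."""
        rng = np.random.default_rng(13)
        X = self.make_X(rng, n=50, p=8, rank=3)
        dec = spectral_decomposition(X, center=False)
        assert dec.rank == 3
        G_wy = 0.1 * rng.standard_normal(3)
        beta = pc_si(dec, G_wy, 3).beta
        W = dec.scores(3)
        gamma = np.linalg.solve(W.T @ W / (dec.n - 1), G_wy)
        assert np.allclose(X @ beta, W @ gamma, atol=1e-8)

    def test_q_beyond_rank_rejected(self):
        rng = np.random.default_rng(14)
        X = self.make_X(rng, n=50, p=8, rank=3)
        dec = spectral_decomposition(X, center=False)
        with pytest.raises(ValueError, match="rank=3"):
            pc_si(dec, np.zeros(8), 5)

    def test_decomposition_invariants(self):
        rng = np.random.default_rng(15)
        X = self.make_X(rng, n=30, p=5)
        dec = spectral_decomposition(X, center=False)
        assert np.allclose(dec.U.T @ dec.U, np.eye(5), atol=1e-8)
        assert np.allclose(dec.V.T @ dec.V, np.eye(5), atol=1e-8)
        assert np.allclose(dec.U * dec.D @ dec.V.T, X, atol=1e-6)


class TestComputeIndex:
    def test_zero_and_unit_vectors(self):
        from regsi.index_solvers import IndexCoefficients
        rng = np.random.default_rng(16)
        X = rng.standard_normal((10, 4))
        zero = IndexCoefficients(np.zeros(4), method="L1")
        assert np.all(compute_index(X, zero) == 0)
        e2 = np.zeros(4)
        e2[2] = 1.0
        unit = IndexCoefficients(e2, method="standard")
        assert np.allclose(compute_index(X, unit), X[:, 2])

    def test_matches_row_loop(self):
        from regsi.index_solvers import IndexCoefficients
        rng = np.random.default_rng(17)
        X = rng.standard_normal((20, 5))
        beta = rng.standard_normal(5)
        coef = IndexCoefficients(beta, method="standard")
        vals = compute_index(X, coef)
        for i in range(20):
            assert vals[i] == pytest.approx(
                sum(X[i, j] * beta[j] for j in range(5)), abs=1e-12)

    def test_label_mismatch(self):
        from regsi.index_solvers import IndexCoefficients
        coef = IndexCoefficients(np.ones(2), method="standard",
                                 band_labels=["a", "b"])
        with pytest.raises(ValueError, match="mismatch"):
            compute_index(np.ones((3, 2)), coef, band_labels=["a", "c"])


class TestReductionChain:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.integers(2, 8))
    def test_solver_family_consistency(self, seed, p):
        """EN(alpha=0) = ridge; ridge(0) = standard; EN(alpha=1) = LARS;
        PC(q=p) = standard — on random instances."""
        rng = np.random.default_rng(seed)
        n = 6 * p
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        P = phenotypic_covariance(X)
        G = 0.3 * rng.standard_normal(p)
        cov = CovariancePair(P, G, 1.0)
        lam = 0.3 * np.max(np.abs(G))

        ridge = l2_psi(cov, lam).beta
        en0 = elastic_net_psi(cov, lambda_grid=[lam], alpha=0.0)
        assert np.allclose(en0.coefficients[0].beta, ridge, atol=1e-8)

        std = standard_si(cov).beta
        assert np.allclose(l2_psi(cov, 0.0).beta, std, atol=1e-10)

        en1 = elastic_net_psi(cov, lambda_grid=[lam], alpha=1.0)
        lars = lars_psi(cov)
        assert np.allclose(en1.coefficients[0].beta, lars.at(lam).beta,
                           atol=1e-5)

        dec = spectral_decomposition(X, center=False)
        assert np.allclose(pc_si(dec, dec.V.T @ G, p).beta, std, atol=1e-8)
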