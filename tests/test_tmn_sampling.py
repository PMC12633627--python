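"""Truncated matrix-normal samplers against closed-form and rejection oracles."""

import numpy as np
import pytest
from scipy import stats

from basin import (
    TMNSpec,
    choose_sampler,
    sample_matrix_normal,
    sample_rectified_mn,
    sample_tmn_gibbs,
    truncated_normal_lower,
)


def _truncated_mean(mu, sigma):
    """Closed-form mean of N(mu, sigma²) truncated to [0, ∞)."""
    alpha = -mu / sigma
    return mu + sigma * stats.norm.pdf(alpha) / stats.norm.sf(alpha)


def _batch_se(x, batch=100):
    """Batch-means standard error for an autocorrelated chain."""
    nb = len(x) // batch
    means = np.asarray(x)[: nb * batch].reshape(nb, batch).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(nb)


class TestChooseSampler:
    @pytest.mark.parametrize(
        "c,p,expected",
        [
            (20, 428, "tmn-gibbs"),   # 8560-dimensional: still exact Gibbs
            (12, 524, "tmn-gibbs"),
            (20, 1000, "rectified"),
        ],
    )
    def test_dimension_threshold(self, c, p, expected):
        assert choose_sampler(c, p) == expected


class TestTruncatedUnivariate:
    def test_output_respects_lower_bound(self, rng):
        draws = [truncated_normal_lower(-2.0, 1.0, u) for u in rng.random(500)]
        assert min(draws) >= 0.0

    def test_deep_tail_is_finite_and_tight(self):
        # lower bound 50 SD above the mean: accept-reject would stall, the
        # log-space inverse CDF must stay accurate
        x = truncated_normal_lower(-50.0, 1.0, 0.5)
        assert np.isfinite(x)
        assert 0.0 <= x < 0.1

    def test_matches_closed_form_cdf(self):
        rng = np.random.default_rng(17)
        mu, sigma = 0.5, 1.3
        draws = np.array(
            [truncated_normal_lower(mu, sigma, u) for u in rng.random(100_000)]
        )
        a = (0.0 - mu) / sigma
        ks = stats.kstest(draws, stats.truncnorm(a, np.inf, loc=mu, scale=sigma).cdf)
        assert ks.pvalue > 0.01


class TestGibbsTMN:
    def test_one_dimensional_marginal(self):
        # 1×1 spec: successive Gibbs draws are iid truncated normal
        rng = np.random.default_rng(23)
        mu, prec = 0.4, 2.0
        spec = TMNSpec(
            M=np.array([[mu]]),
            row_prec=np.array([[prec]]),
            col_prec=np.array([[1.0]]),
        )
        v = np.array([[0.1]])
        draws = np.empty(50_000)
        for k in range(draws.size):
            v = sample_tmn_gibbs(spec, v, sweeps=1, rng=rng)
            draws[k] = v[0, 0]
        sigma = 1.0 / np.sqrt(prec)
        a = -mu / sigma
        ks = stats.kstest(draws, stats.truncnorm(a, np.inf, loc=mu, scale=sigma).cdf)
        assert ks.pvalue > 0.01

    def test_diagonal_precision_independent_coordinates(self):
        # independent coordinates: sample means match the closed-form
        # truncated-normal mean within 3 SE
        rng = np.random.default_rng(31)
        M = np.array([[0.5, -0.3], [1.0, 0.1]])
        spec = TMNSpec(M=M, row_prec=np.eye(2) * 4.0, col_prec=np.eye(2))
        v = np.maximum(M, 0.0)
        total = np.zeros_like(M)
        sq = np.zeros_like(M)
        n = 50_000
        for _ in range(n):
            v = sample_tmn_gibbs(spec, v, sweeps=1, rng=rng)
            total += v
            sq += v**2
        mean = total / n
        sd = np.sqrt(sq / n - mean**2)
        expected = _truncated_mean(M, 0.5)
        np.testing.assert_array_less(np.abs(mean - expected), 3 * sd / np.sqrt(n) + 1e-4)

    def test_correlated_2x2_matches_rejection_oracle(self):
        rng = np.random.default_rng(47)
        M = np.array([[0.3, -0.2], [0.1, 0.4]])
        row_prec = np.array([[2.0, 0.8], [0.8, 1.5]])
        col_prec = np.array([[1.5, -0.6], [-0.6, 2.0]])
        spec = TMNSpec(M=M, row_prec=row_prec, col_prec=col_prec)

        # rejection oracle: sample the untruncated MVN, keep orthant hits
        cov = np.linalg.inv(np.kron(col_prec, row_prec))
        raw = rng.multivariate_normal(M.ravel(order="F"), cov, size=200_000)
        accepted = raw[(raw >= 0).all(axis=1)]
        assert len(accepted) > 5_000
        oracle_mean = accepted.mean(axis=0)
        oracle_se = accepted.std(axis=0, ddof=1) / np.sqrt(len(accepted))

        v = np.maximum(M, 0.0)
        chain = np.empty((100_000, 4))
        for k in range(chain.shape[0]):
            v = sample_tmn_gibbs(spec, v, sweeps=1, rng=rng)
            chain[k] = v.ravel(order="F")
        chain = chain[1_000:]
        gibbs_mean = chain.mean(axis=0)
        gibbs_se = np.array([_batch_se(chain[:, k]) for k in range(4)])
        tol = 3 * np.sqrt(oracle_se**2 + gibbs_se**2)
        np.testing.assert_array_less(np.abs(gibbs_mean - oracle_mean), tol)

    def test_moments_stable_across_sweep_counts(self):
        # detailed-balance smoke test: extra sweeps per draw must not move
        # the stationary moments
        M = np.array([[0.2, 0.5], [-0.1, 0.3]])
        row_prec = np.array([[3.0, 1.0], [1.0, 2.0]])
        col_prec = np.array([[2.0, -0.5], [-0.5, 1.0]])
        spec = TMNSpec(M=M, row_prec=row_prec, col_prec=col_prec)
        means = {}
        for sweeps in (50, 500):
            rng = np.random.default_rng(7)
            v = np.maximum(M, 0.0)
            draws = np.empty((400, 4))
            for k in range(draws.shape[0]):
                v = sample_tmn_gibbs(spec, v, sweeps=sweeps, rng=rng)
                draws[k] = v.ravel()
            means[sweeps] = draws.mean(axis=0)
        assert np.all(np.abs(means[50] - means[500]) < 0.1)

    def test_random_scan_supported(self, rng):
        spec = TMNSpec(M=np.zeros((2, 2)), row_prec=np.eye(2), col_prec=np.eye(2))
        out = sample_tmn_gibbs(spec, np.zeros((2, 2)), rng=rng, scan="random")
        assert np.all(out >= 0)

    def test_rejects_negative_init(self, rng):
        spec = TMNSpec(M=np.zeros((1, 1)), row_prec=np.eye(1), col_prec=np.eye(1))
        with pytest.raises(ValueError, match="nonnegative"):
            sample_tmn_gibbs(spec, np.array([[-0.1]]), rng=rng)

    def test_outputs_nonnegative(self, rng):
        spec = TMNSpec(
            M=-np.ones((3, 4)), row_prec=np.eye(3) * 2, col_prec=np.eye(4)
        )
        out = sample_tmn_gibbs(spec, np.zeros((3, 4)), sweeps=3, rng=rng)
        assert np.all(out >= 0)


class TestMatrixNormal:
    def test_zero_factors_return_mean(self, rng):
        M = rng.random((2, 3))
        out = sample_matrix_normal(M, np.zeros((2, 2)), np.zeros((3, 3)), rng)
        np.testing.assert_array_equal(out, M)

    def test_identity_covariance_moments(self):
        rng = np.random.default_rng(3)
        draws = np.array(
            [
                sample_matrix_normal(np.zeros((2, 2)), np.eye(2), np.eye(2), rng).ravel()
                for _ in range(50_000)
            ]
        )
        cov = np.cov(draws.T)
        np.testing.assert_allclose(cov, np.eye(4), atol=3 / np.sqrt(50_000) * 2)

    def test_vec_covariance_is_kronecker(self):
        # the vec of a matrix-normal draw has covariance colcov ⊗ rowcov
        rng = np.random.default_rng(13)
        R = np.array([[1.0, 0.0], [0.4, 0.8]])
        C = np.array([[0.9, 0.0], [-0.3, 0.6]])
        draws = np.array(
            [
                sample_matrix_normal(np.zeros((2, 2)), R, C, rng).ravel(order="F")
                for _ in range(100_000)
            ]
        )
        expected = np.kron(C @ C.T, R @ R.T)
        np.testing.assert_allclose(np.cov(draws.T), expected, atol=0.02)


class TestRectified:
    def test_high_mean_barely_clamped(self, rng):
        spec = TMNSpec(
            M=np.full((2, 2), 10.0),
            row_prec=np.eye(2) * 1e4,
            col_prec=np.eye(2) * 1e4,
        )
        out = sample_rectified_mn(spec, rng)
        np.testing.assert_allclose(out, 10.0, atol=0.1)

    def test_deep_negative_mean_all_zero(self, rng):
        spec = TMNSpec(
            M=np.full((2, 2), -10.0),
            row_prec=np.eye(2) * 1e4,
            col_prec=np.eye(2) * 1e4,
        )
        np.testing.assert_array_equal(sample_rectified_mn(spec, rng), 0.0)

    def test_half_mass_clamped_at_zero_mean(self):
        rng = np.random.default_rng(29)
        spec = TMNSpec(M=np.zeros((5, 5)), row_prec=np.eye(5), col_prec=np.eye(5))
        frac = np.mean(
            [np.mean(sample_rectified_mn(spec, rng) == 0.0) for _ in range(2_000)]
        )
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_approximates_truncated_when_truncation_mild(self):
        # < 1% sub-zero mass: rectified and Gibbs-truncated means agree to 0.01
        rng = np.random.default_rng(41)
        M = np.full((2, 2), 1.0)
        spec = TMNSpec(M=M, row_prec=np.eye(2) * 16.0, col_prec=np.eye(2))
        # marginal sd 0.25 -> P(draw < 0) = Phi(-4) ≈ 3e-5
        rect = np.mean([sample_rectified_mn(spec, rng) for _ in range(20_000)], axis=0)
        v = M.copy()
        acc = np.zeros_like(M)
        n = 20_000
        for _ in range(n):
            v = sample_tmn_gibbs(spec, v, sweeps=1, rng=rng)
            acc += v
        np.testing.assert_array_less(np.abs(rect - acc / n), 0.01)
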