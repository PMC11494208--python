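"""Gaussian summaries and closed-form divergences against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mindful.divergence import (
    GaussianSummary,
    alt_divergence,
    gaussian_kld,
    gaussian_summary,
)


def random_gaussian(rng, k):
    mean = rng.normal(0, 1, k)
    A = rng.normal(0, 1, (k, k))
    cov = A @ A.T + 0.1 * np.eye(k)
    return GaussianSummary(mean=mean, cov=cov, n=10_000)


def random_affine_map(rng, k, cond_max=50.0):
    """Invertible map with bounded condition number (keeps rounding below tol)."""
    q1 = np.linalg.qr(rng.normal(0, 1, (k, k)))[0]
    q2 = np.linalg.qr(rng.normal(0, 1, (k, k)))[0]
    s = rng.uniform(1.0, cond_max ** 0.5, k) * rng.choice([1.0, 1.0 / cond_max ** 0.5], k)
    return q1 @ np.diag(s) @ q2, rng.normal(0, 2, k)


class TestGaussianSummary:
    def test_two_point_closed_form(self):
        s = gaussian_summary(np.array([[0.0, 0.0], [2.0, 0.0]]))
        np.testing.assert_allclose(s.mean, [1.0, 0.0])
        # unbiased covariance of {0,2} is 2; the singular axis draws a ridge
        assert s.cov[0, 0] == pytest.approx(2.0, rel=1e-6)
        assert s.ridge_applied > 0

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(0)
        mean = np.array([1.0, -2.0, 0.5])
        A = rng.normal(0, 1, (3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        x = rng.multivariate_normal(mean, cov, size=100_000)
        s = gaussian_summary(x)
        assert np.linalg.norm(s.cov - cov) / np.linalg.norm(cov) < 0.02
        np.testing.assert_allclose(s.mean, mean, atol=0.05)

    def test_window_sized_sample_needs_no_ridge(self):
        rng = np.random.default_rng(1)
        s = gaussian_summary(rng.normal(0, 1, (3000, 9)))
        assert s.ridge_applied == 0.0

    def test_undersampled_covariance_is_conditioned(self):
        rng = np.random.default_rng(2)
        s = gaussian_summary(rng.normal(0, 1, (5, 9)))
        assert s.ridge_applied > 0
        np.linalg.cholesky(s.cov)  # must be positive definite

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="at least 2"):
            gaussian_summary(np.ones((1, 3)))


class TestKld:
    def test_zero_at_equality(self):
        rng = np.random.default_rng(3)
        P = random_gaussian(rng, 4)
        assert gaussian_kld(P, P) == pytest.approx(0.0, abs=1e-10)

    def test_univariate_mean_shift_half(self):
        # k=1, unit variances, unit mean shift: 0.5 * (1 + 1 - 1 + 0) = 0.5
        P1 = GaussianSummary(np.array([0.0]), np.array([[1.0]]), 100)
        P2 = GaussianSummary(np.array([1.0]), np.array([[1.0]]), 100)
        assert gaussian_kld(P1, P2) == pytest.approx(0.5, abs=1e-12)

    def test_matches_monte_carlo_oracle(self):
        """Closed form vs E_P1[log p1 - log p2] sampled at n = 10^5."""
        rng = np.random.default_rng(4)
        for k in (1, 2, 3):
            P1, P2 = random_gaussian(rng, k), random_gaussian(rng, k)
            x = rng.multivariate_normal(P1.mean, P1.cov, size=100_000)
            lr = stats.multivariate_normal.logpdf(
                x, P1.mean, P1.cov
            ) - stats.multivariate_normal.logpdf(x, P2.mean, P2.cov)
            est, se = lr.mean(), lr.std(ddof=1) / np.sqrt(len(lr))
            assert abs(gaussian_kld(P1, P2) - est) < 3 * se

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="dimension"):
            gaussian_kld(random_gaussian(rng, 2), random_gaussian(rng, 3))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_nonnegative_and_asymmetric_in_general(self, seed, k):
        rng = np.random.default_rng(seed)
        P1, P2 = random_gaussian(rng, k), random_gaussian(rng, k)
        d12, d21 = gaussian_kld(P1, P2), gaussian_kld(P2, P1)
        assert d12 >= 0.0 and d21 >= 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, seed):
        """Shared invertible affine map leaves the sample KLD unchanged."""
        rng = np.random.default_rng(seed)
        k = 4
        x1 = rng.normal(0, 1, (400, k)) @ rng.normal(0, 1, (k, k)) + rng.normal(0, 1, k)
        x2 = rng.normal(0, 1.3, (400, k)) + 0.5
        A, b = random_affine_map(rng, k)
        base = gaussian_kld(gaussian_summary(x1), gaussian_summary(x2))
        mapped = gaussian_kld(
            gaussian_summary(x1 @ A.T + b), gaussian_summary(x2 @ A.T + b)
        )
        assert abs(base - mapped) < 1e-6


class TestAltDivergences:
    @pytest.mark.parametrize("kind", ["jeffreys", "bhattacharyya", "wasserstein2"])
    def test_zero_at_equality(self, kind):
        rng = np.random.default_rng(6)
        P = random_gaussian(rng, 3)
        # the W2 distance is a square root, which amplifies rounding
        tol = 1e-6 if kind == "wasserstein2" else 1e-8
        assert alt_divergence(P, P, kind) == pytest.approx(0.0, abs=tol)

    def test_jeffreys_symmetric_kld_not(self):
        rng = np.random.default_rng(7)
        P1, P2 = random_gaussian(rng, 3), random_gaussian(rng, 3)
        assert alt_divergence(P1, P2, "jeffreys") == pytest.approx(
            alt_divergence(P2, P1, "jeffreys"), rel=1e-10
        )
        assert gaussian_kld(P1, P2) != pytest.approx(gaussian_kld(P2, P1), rel=1e-3)

    def test_univariate_closed_forms(self):
        """Scalar cases against hand algebra."""
        m1, v1, m2, v2 = 0.0, 1.0, 2.0, 4.0
        P1 = GaussianSummary(np.array([m1]), np.array([[v1]]), 100)
        P2 = GaussianSummary(np.array([m2]), np.array([[v2]]), 100)
        vbar = (v1 + v2) / 2
        bhat = (m2 - m1) ** 2 / (8 * vbar) + 0.5 * np.log(
            vbar / np.sqrt(v1 * v2)
        )
        w2 = np.sqrt((m2 - m1) ** 2 + (np.sqrt(v1) - np.sqrt(v2)) ** 2)
        assert alt_divergence(P1, P2, "bhattacharyya") == pytest.approx(bhat, rel=1e-12)
        assert alt_divergence(P1, P2, "wasserstein2") == pytest.approx(w2, rel=1e-12)
        kld12 = 0.5 * (v1 / v2 + (m2 - m1) ** 2 / v2 - 1 + np.log(v2 / v1))
        kld21 = 0.5 * (v2 / v1 + (m1 - m2) ** 2 / v1 - 1 + np.log(v1 / v2))
        assert alt_divergence(P1, P2, "jeffreys") == pytest.approx(
            kld12 + kld21, rel=1e-12
        )

    def test_bhattacharyya_matches_sampling_oracle(self):
        """-ln integral sqrt(p1 p2) estimated as -ln E_P1[sqrt(p2/p1)]."""
        rng = np.random.default_rng(8)
        P1, P2 = random_gaussian(rng, 2), random_gaussian(rng, 2)
        x = rng.multivariate_normal(P1.mean, P1.cov, size=400_000)
        ratio = np.exp(
            0.5
            * (
                stats.multivariate_normal.logpdf(x, P2.mean, P2.cov)
                - stats.multivariate_normal.logpdf(x, P1.mean, P1.cov)
            )
        )
        est = -np.log(ratio.mean())
        assert alt_divergence(P1, P2, "bhattacharyya") == pytest.approx(est, abs=0.02)

    def test_unknown_kind_rejected(self):
        rng = np.random.default_rng(9)
        P = random_gaussian(rng, 2)
        with pytest.raises(ValueError, match="unknown divergence"):
            alt_divergence(P, P, "hellinger")
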