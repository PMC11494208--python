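"""Gaussian summaries and closed-form divergences between them.

The drift statistic compares two collections of derived neural features
only through their first two moments.  Each collection is reduced to a
:class:`GaussianSummary` (sample mean, unbiased sample covariance, count)
and pairs of summaries are scored with the Kullback-Leibler divergence
between the corresponding multivariate normals,

    d_KL(P1 || P2) = 1/2 [ tr(S2^-1 S1) + (m2-m1)^T S2^-1 (m2-m1)
                           - k + ln(det S2 / det S1) ],

evaluated through Cholesky factors (triangular solves; log-determinants
from factor diagonals) rather than explicit inverses.  Jeffreys,
Bhattacharyya and 2-Wasserstein alternatives share the same summaries.
The KLD is motivated by a Gaussian model but is used as a moment-based
score; no distributional assumption is required of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianSummary",
    "gaussian_summary",
    "gaussian_kld",
    "alt_divergence",
]


class CovarianceConditioningError(ValueError):
    """A covariance could not be made positive definite."""


@dataclass(frozen=True)
class GaussianSummary:
    """Sample mean, covariance and count of one window or reference set."""

    mean: np.ndarray          # (k,)
    cov: np.ndarray           # (k, k), symmetric positive definite
    n: int
    ridge_applied: float = 0.0

    @property
    def k(self) -> int:
        return self.mean.shape[0]

    def _chol(self) -> np.ndarray:
        try:
            return linalg.cholesky(self.cov, lower=True)
        except linalg.LinAlgError as err:
            raise CovarianceConditioningError(
                f"covariance (k={self.k}, n={self.n}) not positive definite"
            ) from err


_MAX_COND = 1e8
_RIDGE_START = 1e-8


def gaussian_summary(samples: np.ndarray, ridge: float = 0.0) -> GaussianSummary:
    """Summarize an (n, k) sample matrix as mean + unbiased covariance.

    If the covariance is ill-conditioned (condition number above 1e8) or the
    sample count does not support an invertible estimate (n <= k), a ridge of
    ``r * trace(S)/k`` is added to the diagonal, with ``r`` escalating by
    factors of 10 from 1e-8 until the matrix factorizes; the total ridge used
    is recorded on the summary.  An explicit ``ridge`` argument seeds the
    escalation instead.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D (n, k) array")
    n, k = samples.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")

    mean = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1).reshape(k, k)
    cov = 0.5 * (cov + cov.T)

    scale = np.trace(cov) / k
    if scale <= 0:
        scale = 1.0

    def needs_ridge(c: np.ndarray) -> bool:
        try:
            linalg.cholesky(c, lower=True)
        except linalg.LinAlgError:
            return True
        w = linalg.eigvalsh(c)
        return bool(w[0] <= 0 or w[-1] / max(w[0], np.finfo(float).tiny) > _MAX_COND)

    total_ridge = 0.0
    if ridge > 0:
        cov = cov + ridge * scale * np.eye(k)
        total_ridge = ridge * scale
    if n <= k or needs_ridge(cov):
        r = ridge if ridge > 0 else _RIDGE_START
        for _ in range(20):
            cand = cov + r * scale * np.eye(k)
            try:
                linalg.cholesky(cand, lower=True)
            except linalg.LinAlgError:
                r *= 10.0
                continue
            w = linalg.eigvalsh(cand)
            if w[0] > 0 and w[-1] / w[0] <= _MAX_COND:
                cov = cand
                total_ridge += r * scale
                break
            r *= 10.0
        else:  # pragma: no cover - pathological input
            raise CovarianceConditioningError(
                "ridge escalation failed to produce a positive definite "
                f"covariance (k={k}, n={n})"
            )
    return GaussianSummary(mean=mean, cov=cov, n=n, ridge_applied=total_ridge)


def gaussian_kld(P1: GaussianSummary, P2: GaussianSummary) -> float:
    """Closed-form KL divergence d_KL(P1 || P2) between Gaussian summaries.

    Always >= 0 (clipped against rounding); 0 iff the summaries coincide.
    Asymmetric: the second argument's covariance is the one inverted, so a
    shrunken comparison covariance inflates the score.
    """
    if P1.k != P2.k:
        raise ValueError(f"dimension mismatch: {P1.k} vs {P2.k}")
    k = P1.k
    L1 = P1._chol()
    L2 = P2._chol()
    # tr(S2^-1 S1) = ||L2^-1 L1||_F^2
    A = linalg.solve_triangular(L2, L1, lower=True)
    trace_term = float(np.sum(A * A))
    y = linalg.solve_triangular(L2, P2.mean - P1.mean, lower=True)
    quad = float(y @ y)
    logdet1 = 2.0 * float(np.sum(np.log(np.diag(L1))))
    logdet2 = 2.0 * float(np.sum(np.log(np.diag(L2))))
    return max(0.5 * (trace_term + quad - k + logdet2 - logdet1), 0.0)


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD matrix square root via eigendecomposition."""
    w, v = linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def alt_divergence(P1: GaussianSummary, P2: GaussianSummary, kind: str) -> float:
    """Alternate closed-form Gaussian dissimilarities.

    kind:
      ``jeffreys``      symmetric KL, d(P1||P2) + d(P2||P1)
      ``bhattacharyya`` (1/8) dm^T Sbar^-1 dm + (1/2) ln(det Sbar /
                        sqrt(det S1 det S2)), Sbar = (S1+S2)/2
      ``wasserstein2``  the 2-Wasserstein *distance* (square root of the
                        closed-form squared distance
                        ||dm||^2 + tr(S1 + S2 - 2 (S2^1/2 S1 S2^1/2)^1/2))
    """
    if P1.k != P2.k:
        raise ValueError(f"dimension mismatch: {P1.k} vs {P2.k}")
    if kind == "jeffreys":
        return gaussian_kld(P1, P2) + gaussian_kld(P2, P1)
    if kind == "bhattacharyya":
        sbar = 0.5 * (P1.cov + P2.cov)
        Lb = linalg.cholesky(sbar, lower=True)
        y = linalg.solve_triangular(Lb, P2.mean - P1.mean, lower=True)
        quad = float(y @ y) / 8.0
        logdet_bar = 2.0 * float(np.sum(np.log(np.diag(Lb))))
        logdet1 = 2.0 * float(np.sum(np.log(np.diag(P1._chol()))))
        logdet2 = 2.0 * float(np.sum(np.log(np.diag(P2._chol()))))
        return max(quad + 0.5 * (logdet_bar - 0.5 * (logdet1 + logdet2)), 0.0)
    if kind == "wasserstein2":
        dm = P1.mean - P2.mean
        s2h = _sqrtm_psd(P2.cov)
        cross = _sqrtm_psd(s2h @ P1.cov @ s2h)
        sq = float(dm @ dm) + float(np.trace(P1.cov + P2.cov - 2.0 * cross))
        return float(np.sqrt(max(sq, 0.0)))
    raise ValueError(f"unknown divergence kind {kind!r}")
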