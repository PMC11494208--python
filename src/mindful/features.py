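"""Derived neural features: causal rolling z-score, reference PCA, decoder
output and its one-bin lag.

The drift statistic never sees raw counts.  Each channel is standardized
with a trailing 3-min rolling window (restarting at block boundaries, with
an expanding-window warm-up), the z-scored population is optionally
projected onto the top-M principal components of a *reference* bin set, and
the decoded 2-D velocity and its 20-ms-lagged copy can be appended.  The
default 9-dimensional composition is 5 PCs + velocity + lagged velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .session import BinnedSession

logger = logging.getLogger(__name__)

__all__ = [
    "rolling_zscore",
    "ReferencePCA",
    "fit_reference_pca",
    "project_pca",
    "DerivedFeatures",
    "build_derived_features",
    "DEFAULT_COMPOSITION",
]

#: window length (s) of the causal rolling z-score
ZSCORE_WINDOW_S = 180.0
#: minimum expanding-window length (s) before a bin counts as valid
ZSCORE_WARMUP_S = 30.0
#: variance clamp, in z-units^2, protecting silent channels
VAR_FLOOR = 1e-6

DEFAULT_COMPOSITION: tuple[str, ...] = ("pc", "xhat", "xhat_lag")


def rolling_zscore(
    features: np.ndarray,
    bin_width: float,
    block_id: np.ndarray | None = None,
    window_s: float = ZSCORE_WINDOW_S,
    warmup_s: float = ZSCORE_WARMUP_S,
    var_floor: float = VAR_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal per-channel standardization with a trailing rolling window.

    Each bin ``t`` is standardized with the mean and (population) variance
    of the trailing window ending at and including ``t``; for the first
    ``window_s`` of a block the window expands from the block start.
    Statistics never cross block boundaries.  Bins whose expanding window is
    shorter than ``warmup_s`` are computed but flagged invalid, and excluded
    from reference and comparison windows downstream.

    Returns
    -------
    z : ndarray (T, C)
    valid : ndarray (T,) of bool
    """
    x = np.asarray(features, dtype=float)
    T, C = x.shape
    if window_s < 10 * bin_width:
        raise ValueError("z-score window must be at least 10 bins")
    W = max(int(round(window_s / bin_width)), 1)
    warm = max(int(round(warmup_s / bin_width)), 1)

    if block_id is None:
        starts = np.array([0])
    else:
        block_id = np.asarray(block_id)
        starts = np.concatenate(([0], np.flatnonzero(np.diff(block_id)) + 1))
    bounds = list(starts) + [T]

    z = np.empty_like(x)
    valid = np.zeros(T, dtype=bool)
    clamped_channels: set[int] = set()
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = x[b0:b1]
        n_seg = b1 - b0
        c1 = np.cumsum(seg, axis=0)
        c2 = np.cumsum(seg * seg, axis=0)
        t = np.arange(n_seg)
        lo = np.maximum(t - W + 1, 0)       # window start (inclusive)
        n = (t - lo + 1).astype(float)[:, None]
        s1 = c1 - np.where(lo[:, None] > 0, c1[lo - 1], 0.0)
        s2 = c2 - np.where(lo[:, None] > 0, c2[lo - 1], 0.0)
        mean = s1 / n
        var = s2 / n - mean * mean
        floored = var < var_floor
        if floored.any():
            for ch in np.unique(np.nonzero(floored)[1]):
                if ch not in clamped_channels:
                    clamped_channels.add(int(ch))
        var = np.maximum(var, var_floor)
        z[b0:b1] = (seg - mean) / np.sqrt(var)
        valid[b0:b1] = t + 1 >= warm
    if clamped_channels:
        logger.info(
            "rolling_zscore: variance clamped at %g for %d channel(s)",
            var_floor, len(clamped_channels),
        )
    return z, valid


class ReferencePCA(BaseEstimator, TransformerMixin):
    """PCA basis fitted on z-scored reference bins, with deterministic signs.

    Thin estimator around :class:`sklearn.decomposition.PCA` (full SVD
    solver).  After fitting, every loading row is flipped so its
    largest-magnitude entry is positive, making the basis reproducible
    across runs and platforms.

    Attributes
    ----------
    center_ : ndarray (C,)
        Mean of the reference bins.
    components_ : ndarray (M, C)
        Orthonormal loading rows ordered by descending explained variance.
    explained_variance_ratio_ : ndarray (M,)
    """

    def __init__(self, n_components: int = 5, fitted_on: str | None = None):
        self.n_components = n_components
        self.fitted_on = fitted_on

    def fit(self, X: np.ndarray, y=None) -> "ReferencePCA":
        X = np.asarray(X, dtype=float)
        n, C = X.shape
        rank = min(n, C)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds data rank bound {rank}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        comps = pca.components_.copy()
        for row in comps:
            j = np.argmax(np.abs(row))
            if row[j] < 0:
                row *= -1.0
        self.center_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = C
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} channels, basis expects {self.n_features_in_}"
            )
        return (X - self.center_) @ self.components_.T


def fit_reference_pca(zfeatures: np.ndarray, n_components: int = 5) -> ReferencePCA:
    """Fit the top-``n_components`` PCA basis of a z-scored reference set."""
    return ReferencePCA(n_components=n_components).fit(zfeatures)


def project_pca(basis: ReferencePCA, zfeatures: np.ndarray) -> np.ndarray:
    """Project z-scored features onto a fitted reference basis."""
    return basis.transform(zfeatures)


@dataclass
class DerivedFeatures:
    """T x k matrix of drift-statistic inputs plus a per-bin validity mask.

    ``composition`` records the ordered column blocks: ``"pc"`` (M PCA
    projections), ``"xhat"`` (decoded velocity, 2 columns), ``"xhat_lag"``
    (decoded velocity from the previous bin, 2 columns).  Bins invalid for
    window statistics (z-score warm-up; first bin of each block for the lag)
    are flagged in ``valid``.
    """

    values: np.ndarray        # (T, k)
    valid: np.ndarray         # (T,)
    composition: tuple[str, ...]
    session_day: int

    @property
    def k(self) -> int:
        return self.values.shape[1]


def build_derived_features(
    session: BinnedSession,
    basis: ReferencePCA | None = None,
    composition: Sequence[str] = DEFAULT_COMPOSITION,
    zfeatures: np.ndarray | None = None,
    z_valid: np.ndarray | None = None,
    window_s: float = ZSCORE_WINDOW_S,
    warmup_s: float = ZSCORE_WARMUP_S,
    var_floor: float = VAR_FLOOR,
) -> DerivedFeatures:
    """Assemble the derived feature matrix for one session.

    Column blocks are concatenated in the declared ``composition`` order.
    Passing precomputed ``zfeatures``/``z_valid`` (from
    :func:`rolling_zscore`) avoids recomputation across analyses.
    """
    composition = tuple(composition)
    if not composition:
        raise ValueError("composition must not be empty")
    unknown = set(composition) - {"pc", "xhat", "xhat_lag"}
    if unknown:
        raise ValueError(f"unknown composition tags: {sorted(unknown)}")

    T = session.n_bins
    if zfeatures is None or z_valid is None:
        zfeatures, z_valid = rolling_zscore(
            session.features, session.bin_width, session.block_id,
            window_s=window_s, warmup_s=warmup_s, var_floor=var_floor,
        )
    valid = z_valid.copy()

    blocks: list[np.ndarray] = []
    for tag in composition:
        if tag == "pc":
            if basis is None:
                raise ValueError("composition includes 'pc' but no basis given")
            blocks.append(basis.transform(zfeatures))
        elif tag == "xhat":
            blocks.append(session.decoded_velocity)
        elif tag == "xhat_lag":
            lag = np.roll(session.decoded_velocity, 1, axis=0)
            lag[0] = 0.0
            blocks.append(lag)
            valid &= np.arange(T) != 0
            for b0 in session.block_starts():
                valid[b0] = False
    values = np.concatenate(blocks, axis=1) if blocks else np.empty((T, 0))
    return DerivedFeatures(
        values=values, valid=valid, composition=composition,
        session_day=session.session_day,
    )
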