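"""Direction-dependent latent-space drift via demixed direction components.

Trial-averaged, Gaussian-smoothed population trajectories are computed per
movement direction (eight 45-deg sectors).  On the first session, rank-2
encoder/decoder components (F: C x 2, D: 2 x C) are fitted so that F D Ybar
best reconstructs the direction-dependent part of the condition-averaged
activity Ybar (unregularized analytic reduced-rank regression).  Later
sessions are projected through the *fixed* day-0 components, and drift is
summarized by the variance accounted for

    R^2 = (||Ybar||^2 - ||Ybar - F D Ybar||^2) / ||Ybar||^2

(Frobenius norms), which shrinks as the population's direction coding
rotates away from the day-0 subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .session import BinnedSession
from .tuning import REACTION_TIME_S, TUNING_WINDOW_S

logger = logging.getLogger(__name__)

__all__ = [
    "condition_average",
    "ConditionAverage",
    "DirectionalDPCA",
    "fit_direction_dpca",
    "vaf",
    "correlate_vaf_with_mean_kld",
]

SMOOTHING_SD_S = 0.050


def _gaussian_kernel(sd_bins: float) -> np.ndarray:
    """Discrete Gaussian kernel normalized to unit mass."""
    radius = max(int(np.ceil(4 * sd_bins)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    return k / k.sum()


@dataclass
class ConditionAverage:
    """Per-direction trial-averaged smoothed trajectories, concatenated.

    ``values`` is C x (n_present * n_time); ``directions`` lists the sector
    centres (deg) actually present, in ascending order.
    """

    values: np.ndarray
    directions: np.ndarray
    n_time: int

    def block(self, direction_deg: float) -> np.ndarray:
        i = int(np.flatnonzero(self.directions == direction_deg)[0])
        return self.values[:, i * self.n_time : (i + 1) * self.n_time]


def condition_average(
    session: BinnedSession,
    zfeatures: np.ndarray,
    n_directions: int = 8,
    smoothing_sd_s: float = SMOOTHING_SD_S,
    reaction_time_s: float = REACTION_TIME_S,
    window_s: float = TUNING_WINDOW_S,
) -> ConditionAverage:
    """Direction-conditioned trial averages over the reach window.

    Non-outlier trials long enough for the full window are assigned to the
    45-deg sector (centres 0, 45, ..., 315) nearest their intended direction
    at the go cue, averaged within sector, and smoothed along time with a
    unit-mass Gaussian kernel (sd 50 ms).  Empty sectors are omitted
    (logged).
    """
    off = int(round(reaction_time_s / session.bin_width))
    span = int(round(window_s / session.bin_width))
    sector_width = 360.0 / n_directions
    buckets: dict[int, list[np.ndarray]] = {d: [] for d in range(n_directions)}
    for tr in session.trials:
        if tr.outlier:
            continue
        s = tr.go_cue_bin + off
        e = s + span
        if e > tr.end_bin:
            continue
        d = session.target_pos[tr.go_cue_bin] - session.cursor_pos[tr.go_cue_bin]
        theta = np.degrees(np.arctan2(d[1], d[0])) % 360.0
        sector = int(np.round(theta / sector_width)) % n_directions
        buckets[sector].append(zfeatures[s:e])

    kernel = _gaussian_kernel(smoothing_sd_s / session.bin_width)
    blocks, present = [], []
    for d in range(n_directions):
        if not buckets[d]:
            continue
        avg = np.mean(buckets[d], axis=0)  # (span, C)
        sm = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same"), 0, avg
        )
        blocks.append(sm.T)  # (C, span)
        present.append(d * sector_width)
    missing = n_directions - len(present)
    if missing:
        logger.info("condition_average: %d empty direction sector(s)", missing)
    if not blocks:
        raise ValueError("no direction sector has a complete trial")
    return ConditionAverage(
        values=np.concatenate(blocks, axis=1),
        directions=np.array(present),
        n_time=span,
    )


def _marginalize_direction(avg: ConditionAverage) -> np.ndarray:
    """Direction-dependent part: Ybar minus the direction-mean time course.

    The split is orthogonal: ||Ybar||^2 = ||mean part||^2 + ||dir part||^2.
    """
    C = avg.values.shape[0]
    D = len(avg.directions)
    Y = avg.values.reshape(C, D, avg.n_time)
    return (Y - Y.mean(axis=1, keepdims=True)).reshape(C, D * avg.n_time)


class DirectionalDPCA(BaseEstimator):
    """Rank-2 direction components fitted on one session's condition averages.

    ``fit`` solves the reduced-rank regression of the direction-marginalized
    condition average on the full condition average: the unconstrained
    least-squares map is computed analytically and projected onto the top-2
    principal subspace of its fitted values, yielding encoder ``F_``
    (C x 2) and decoder ``D_`` (2 x C).  ``score`` returns the VAF of a
    later session's condition average through the frozen components.
    """

    def __init__(
        self,
        n_directions: int = 8,
        smoothing_sd_s: float = SMOOTHING_SD_S,
        reaction_time_s: float = REACTION_TIME_S,
        window_s: float = TUNING_WINDOW_S,
    ):
        self.n_directions = n_directions
        self.smoothing_sd_s = smoothing_sd_s
        self.reaction_time_s = reaction_time_s
        self.window_s = window_s

    def _avg(self, session: BinnedSession, zfeatures: np.ndarray) -> ConditionAverage:
        return condition_average(
            session, zfeatures,
            n_directions=self.n_directions,
            smoothing_sd_s=self.smoothing_sd_s,
            reaction_time_s=self.reaction_time_s,
            window_s=self.window_s,
        )

    def fit(self, session: BinnedSession, zfeatures: np.ndarray) -> "DirectionalDPCA":
        avg = self._avg(session, zfeatures)
        if len(avg.directions) < 2:
            raise ValueError("need at least 2 direction sectors to fit")
        self._fit_from_average(avg)
        self.fitted_day_ = session.session_day
        return self

    def _fit_from_average(self, avg: ConditionAverage) -> None:
        Y = avg.values
        Ydir = _marginalize_direction(avg)
        # unconstrained LS map B: Ydir ~ B Y  (solve Y^T B^T = Ydir^T)
        Bt, *_ = np.linalg.lstsq(Y.T, Ydir.T, rcond=None)
        B = Bt.T
        fitted = B @ Y
        U, s, _ = np.linalg.svd(fitted, full_matrices=False)
        if (s > 1e-12 * max(s[0], 1.0)).sum() < 2:
            raise ValueError("direction marginalization has rank < 2")
        F = U[:, :2]
        self.F_ = F
        self.D_ = F.T @ B
        self.day0_average_ = avg

    def project(self, avg: ConditionAverage) -> np.ndarray:
        """Latent trajectories: D Ybar, shape (2, n_present * n_time)."""
        check_is_fitted(self, "F_")
        return self.D_ @ avg.values

    def score(self, session: BinnedSession, zfeatures: np.ndarray) -> float:
        """VAF of this session's condition average through day-0 components."""
        check_is_fitted(self, "F_")
        return vaf(self._avg(session, zfeatures), self)


def fit_direction_dpca(avg: ConditionAverage) -> DirectionalDPCA:
    """Fit rank-2 direction components directly from a condition average."""
    model = DirectionalDPCA()
    if len(avg.directions) < 2:
        raise ValueError("need at least 2 direction sectors to fit")
    model._fit_from_average(avg)
    model.fitted_day_ = -1
    return model


def vaf(avg: ConditionAverage, model: DirectionalDPCA) -> float:
    """Variance accounted for by the frozen rank-2 components.

    ``R^2 = (||Y||^2 - ||Y - F D Y||^2) / ||Y||^2`` with Frobenius norms;
    1 when Y lies in the components' image, <= 0 when the projection adds
    nothing.
    """
    Y = avg.values
    total = float(np.sum(Y * Y))
    if total == 0:
        raise ValueError("zero-norm condition average")
    recon = model.F_ @ (model.D_ @ Y)
    resid = Y - recon
    return (total - float(np.sum(resid * resid))) / total


def correlate_vaf_with_mean_kld(
    vaf_per_session: np.ndarray, mean_kld_day0_row: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of per-session VAF against mean KLD vs day 0."""
    v = np.asarray(vaf_per_session, dtype=float)
    k = np.asarray(mean_kld_day0_row, dtype=float)
    ok = np.isfinite(v) & np.isfinite(k)
    if ok.sum() < 3:
        raise ValueError("need at least 3 sessions")
    if np.std(v[ok]) == 0 or np.std(k[ok]) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(v[ok], k[ok])
    return float(res.statistic), float(res.pvalue)
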