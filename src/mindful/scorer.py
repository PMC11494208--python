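"""The drift statistic: reference selection, sliding-window KLD trace,
AE-binned KLD, and pairwise inter-session mean KLD.

The score compares the distribution of derived neural features inside a
sliding comparison window against a reference distribution collected when
decoding was known to be good (by default, bins with angle error < 4 deg on
the first session, when the decoder was first deployed).  Both
distributions are summarized by sample mean and covariance and compared
with the closed-form Gaussian KL divergence; the reference is the first
argument of the divergence by default, so the comparison window's
covariance is the one inverted.

``MindfulScorer`` is the estimator around this pipeline: ``fit`` learns the
reference (PCA basis fitted on reference bins + reference Gaussian) from a
list of sessions, ``transform`` produces a windowed KLD trace for any
sessions sharing the channel layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .divergence import GaussianSummary, gaussian_kld, gaussian_summary
from .features import (
    DEFAULT_COMPOSITION,
    DerivedFeatures,
    ReferencePCA,
    build_derived_features,
    rolling_zscore,
)
from .metrics import AngleErrorTrace, angle_error, window_grid, windowed_median_ae
from .session import BinnedSession

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceModel",
    "MindfulTrace",
    "MindfulScorer",
    "select_reference_bins",
    "mindful_trace",
    "kld_by_ae_bins",
    "pairwise_session_mean_kld",
]

_SECTOR_AXES = {"right": 0.0, "up": 90.0, "left": 180.0, "down": 270.0}


@dataclass
class ReferenceModel:
    """Reference bin selection, its Gaussian summary, and the PCA basis."""

    bin_masks: dict[int, np.ndarray]       # session_day -> boolean mask
    gaussian: GaussianSummary
    pca_basis: ReferencePCA | None
    selection_rule: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(sum(m.sum() for m in self.bin_masks.values()))


@dataclass
class MindfulTrace:
    """Windowed KLD trace for one session (NaN = window emitted missing)."""

    window_start_s: np.ndarray
    kld: np.ndarray
    n_bins: np.ndarray
    session_day: int
    grid: np.ndarray  # (n_windows, 2) bin spans

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_day": self.session_day,
                "window_start_s": self.window_start_s,
                "kld": self.kld,
                "n_bins": self.n_bins,
            }
        )


def _intent_angles(session: BinnedSession) -> np.ndarray:
    d = session.target_pos - session.cursor_pos
    return np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0


def select_reference_bins(
    sessions: Sequence[BinnedSession],
    ae_traces: Sequence[AngleErrorTrace],
    valid_masks: Sequence[np.ndarray],
    ae_threshold_deg: float | None = 4.0,
    session_days: Sequence[int] | None = None,
    direction_sector: str | None = None,
    exclude_outliers: bool = False,
) -> dict[int, np.ndarray]:
    """Select reference bins: good-performance bins of the deployment day(s).

    Bins must be valid for window statistics (past z-score warm-up, lag
    defined), carry a valid AE below ``ae_threshold_deg`` (skipped when the
    threshold is None, e.g. for task-agnostic references where AE is not
    observable), and optionally have intended direction within +-45 deg of a
    named sector axis.  Raises with per-filter counts if nothing survives.
    """
    if session_days is None:
        session_days = [sessions[0].session_day]
    if direction_sector is not None and direction_sector not in _SECTOR_AXES:
        raise ValueError(f"unknown direction sector {direction_sector!r}")

    masks: dict[int, np.ndarray] = {}
    counts = {"candidate": 0, "after_ae": 0, "after_sector": 0}
    for sess, trace, valid in zip(sessions, ae_traces, valid_masks):
        if sess.session_day not in session_days:
            continue
        m = valid.copy()
        if exclude_outliers:
            m &= ~sess.outlier_bin_mask()
        counts["candidate"] += int(m.sum())
        if ae_threshold_deg is not None:
            m &= trace.valid & (trace.ae < ae_threshold_deg)
        counts["after_ae"] += int(m.sum())
        if direction_sector is not None:
            axis = _SECTOR_AXES[direction_sector]
            ang = _intent_angles(sess)
            diff = np.abs((ang - axis + 180.0) % 360.0 - 180.0)
            m &= diff <= 45.0
        counts["after_sector"] += int(m.sum())
        masks[sess.session_day] = m
    total = sum(int(m.sum()) for m in masks.values())
    if total == 0:
        raise ValueError(f"empty reference selection (filter counts: {counts})")
    return masks


class MindfulScorer(BaseEstimator):
    """Sliding-window drift scorer over derived neural features.

    Parameters
    ----------
    composition : sequence of {"pc", "xhat", "xhat_lag"}
        Ordered derived-feature blocks (default 5 PCs + decoded velocity +
        its one-bin lag, k = 9).
    n_components : int
        PCA components when ``"pc"`` is in the composition.
    ae_threshold_deg : float or None
        Reference bins restricted to angle error below this value (None
        disables AE subsampling).
    reference_days : sequence of int or None
        Session days forming the reference; None means the first session
        passed to ``fit``.
    direction_sector : {"up", "down", "left", "right"} or None
        Optionally restrict reference bins to one intended-direction sector.
    window_s, step_s : float
        Comparison-window length and stride in seconds.
    direction : {"ref_vs_window", "window_vs_ref"}
        Order of arguments to the KL divergence.
    exclude_outliers : bool
        Drop bins inside outlier-flagged trials from reference and windows.

    Attributes
    ----------
    reference_ : ReferenceModel
    pca_ : ReferencePCA or None
    k_ : int
        Derived-feature dimensionality.
    """

    def __init__(
        self,
        composition: Sequence[str] = DEFAULT_COMPOSITION,
        n_components: int = 5,
        ae_threshold_deg: float | None = 4.0,
        reference_days: Sequence[int] | None = None,
        direction_sector: str | None = None,
        window_s: float = 60.0,
        step_s: float = 1.0,
        direction: str = "ref_vs_window",
        exclude_outliers: bool = False,
    ):
        self.composition = tuple(composition)
        self.n_components = n_components
        self.ae_threshold_deg = ae_threshold_deg
        self.reference_days = reference_days
        self.direction_sector = direction_sector
        self.window_s = window_s
        self.step_s = step_s
        self.direction = direction
        self.exclude_outliers = exclude_outliers

    # ------------------------------------------------------------------
    def _prepare(
        self, session: BinnedSession
    ) -> tuple[np.ndarray, np.ndarray, AngleErrorTrace]:
        z, z_valid = rolling_zscore(
            session.features, session.bin_width, session.block_id
        )
        return z, z_valid, angle_error(session)

    def _derived(
        self, session: BinnedSession, z: np.ndarray, z_valid: np.ndarray
    ) -> DerivedFeatures:
        return build_derived_features(
            session,
            basis=self.pca_,
            composition=self.composition,
            zfeatures=z,
            z_valid=z_valid,
        )

    def fit(self, sessions: Sequence[BinnedSession], y=None) -> "MindfulScorer":
        """Learn the reference PCA basis and reference Gaussian."""
        if self.direction not in ("ref_vs_window", "window_vs_ref"):
            raise ValueError(f"unknown direction {self.direction!r}")
        sessions = list(sessions)
        prep = [self._prepare(s) for s in sessions]
        # validity incl. the lag rule, computable before any PCA basis exists
        valid_masks = []
        for sess, (z, z_valid, _) in zip(sessions, prep):
            v = z_valid.copy()
            if "xhat_lag" in self.composition:
                v[0] = False
                v[sess.block_starts()] = False
            valid_masks.append(v)

        days = (
            list(self.reference_days)
            if self.reference_days is not None
            else [sessions[0].session_day]
        )
        ref_masks = select_reference_bins(
            sessions,
            [p[2] for p in prep],
            valid_masks,
            ae_threshold_deg=self.ae_threshold_deg,
            session_days=days,
            direction_sector=self.direction_sector,
            exclude_outliers=self.exclude_outliers,
        )

        if "pc" in self.composition:
            ref_z = np.concatenate(
                [
                    z[ref_masks[s.session_day]]
                    for s, (z, _, _) in zip(sessions, prep)
                    if s.session_day in ref_masks
                ]
            )
            self.pca_ = ReferencePCA(n_components=self.n_components).fit(ref_z)
        else:
            self.pca_ = None

        ref_rows = []
        for sess, (z, z_valid, _) in zip(sessions, prep):
            if sess.session_day not in ref_masks:
                continue
            der = self._derived(sess, z, z_valid)
            ref_rows.append(der.values[ref_masks[sess.session_day]])
        ref_values = np.concatenate(ref_rows)
        self.k_ = ref_values.shape[1]
        self.reference_ = ReferenceModel(
            bin_masks=ref_masks,
            gaussian=gaussian_summary(ref_values),
            pca_basis=self.pca_,
            selection_rule={
                "ae_threshold_deg": self.ae_threshold_deg,
                "session_days": days,
                "direction_sector": self.direction_sector,
            },
        )
        return self

    # ------------------------------------------------------------------
    def _window_kld(self, window: GaussianSummary) -> float:
        ref = self.reference_.gaussian
        if self.direction == "ref_vs_window":
            return gaussian_kld(ref, window)
        return gaussian_kld(window, ref)

    def trace(self, session: BinnedSession) -> MindfulTrace:
        """Windowed KLD trace for one session."""
        check_is_fitted(self, "reference_")
        z, z_valid, _ = self._prepare(session)
        der = self._derived(session, z, z_valid)
        if der.k != self.k_:
            raise ValueError(
                f"derived dimensionality {der.k} != reference {self.k_}; "
                "composition mismatch"
            )
        valid = der.valid.copy()
        if self.exclude_outliers:
            valid &= ~session.outlier_bin_mask()
        grid = window_grid(session, self.window_s, self.step_s)
        kld = np.full(len(grid), np.nan)
        n_bins = np.zeros(len(grid), dtype=int)
        min_n = self.k_ + 2
        for i, (s, e) in enumerate(grid):
            rows = der.values[s:e][valid[s:e]]
            n_bins[i] = rows.shape[0]
            if rows.shape[0] < min_n:
                continue
            kld[i] = self._window_kld(gaussian_summary(rows))
        return MindfulTrace(
            window_start_s=grid[:, 0] * session.bin_width if len(grid) else np.array([]),
            kld=kld,
            n_bins=n_bins,
            session_day=session.session_day,
            grid=grid,
        )

    def transform(self, sessions: Sequence[BinnedSession]) -> pd.DataFrame:
        """Windowed KLD + median AE table, pooled over sessions.

        Columns: ``session_day, window_start_s, kld, n_bins, median_ae``;
        both series share the same trailing window grid.
        """
        frames = []
        for sess in sessions:
            tr = self.trace(sess)
            ae = angle_error(sess)
            extra = sess.outlier_bin_mask() if self.exclude_outliers else None
            ae_masked = AngleErrorTrace(ae=ae.ae, valid=ae.masked(extra))
            med = windowed_median_ae(ae_masked, tr.grid)
            f = tr.to_frame()
            f["median_ae"] = med
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()



def mindful_trace(
    scorer: MindfulScorer, sessions: Sequence[BinnedSession]
) -> list[MindfulTrace]:
    """Per-session KLD traces from a fitted scorer (thin wrapper)."""
    return [scorer.trace(s) for s in sessions]


# ----------------------------------------------------------------------
# AE-binned KLD (performance-grouped proof of concept)
# ----------------------------------------------------------------------

def kld_by_ae_bins(
    sessions: Sequence[BinnedSession],
    bin_width_deg: float = 4.0,
    composition: Sequence[str] = ("pc",),
    n_components: int = 5,
    min_bins: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """KLD between the low-AE reference and 45 AE-graded comparison sets.

    Valid bins pooled across all sessions are grouped by instantaneous AE
    into intervals [0, w), [w, 2w), ..., [180-w, 180]; the reference (and
    the PCA-reference data) is the pooled bins with AE below ``w``.  Each
    interval yields one KLD(reference || interval); empty or underpopulated
    intervals emit NaN and are excluded from the returned Pearson r of KLD
    against interval midpoints.
    """
    n_int = int(round(180.0 / bin_width_deg))
    prep = []
    for sess in sessions:
        z, z_valid = rolling_zscore(sess.features, sess.bin_width, sess.block_id)
        prep.append((sess, z, z_valid, angle_error(sess)))

    ref_z, pooled_rows, pooled_ae = [], [], []
    for sess, z, z_valid, tr in prep:
        m = z_valid & tr.valid
        ref_z.append(z[m & (tr.ae < bin_width_deg)])
    ref_z = np.concatenate(ref_z)
    if ref_z.shape[0] < 2:
        raise ValueError("no bins with AE below the reference interval")
    basis = ReferencePCA(n_components=n_components).fit(ref_z) if "pc" in composition else None

    for sess, z, z_valid, tr in prep:
        der = build_derived_features(
            sess, basis=basis, composition=composition, zfeatures=z, z_valid=z_valid
        )
        m = der.valid & tr.valid
        pooled_rows.append(der.values[m])
        pooled_ae.append(tr.ae[m])
    rows = np.concatenate(pooled_rows)
    ae = np.concatenate(pooled_ae)
    k = rows.shape[1]
    if min_bins is None:
        min_bins = max(k + 2, 20)

    ref_summary = gaussian_summary(rows[ae < bin_width_deg])
    lo = np.arange(n_int) * bin_width_deg
    hi = lo + bin_width_deg
    recs = []
    for i in range(n_int):
        if i == n_int - 1:
            sel = (ae >= lo[i]) & (ae <= hi[i])  # closing interval includes 180
        else:
            sel = (ae >= lo[i]) & (ae < hi[i])
        n = int(sel.sum())
        kld = np.nan
        if n >= min_bins:
            kld = gaussian_kld(ref_summary, gaussian_summary(rows[sel]))
        recs.append({"ae_lo": lo[i], "ae_hi": hi[i],
                     "ae_mid": 0.5 * (lo[i] + hi[i]), "kld": kld, "n": n})
    table = pd.DataFrame(recs)
    ok = table["kld"].notna()
    if ok.sum() >= 3:
        r = float(stats.pearsonr(table.loc[ok, "ae_mid"], table.loc[ok, "kld"]).statistic)
    else:
        r = np.nan
    return table, r


# ----------------------------------------------------------------------
# Pairwise inter-session mean KLD
# ----------------------------------------------------------------------

def pairwise_session_mean_kld(
    sessions: Sequence[BinnedSession],
    scorer: MindfulScorer,
    window_s: float = 60.0,
    step_s: float = 10.0,
    exclude_outliers: bool = True,
) -> pd.DataFrame:
    """S x S matrix of mean KLD between all window pairs of session pairs.

    Entry (i, j) averages KLD(window of i || window of j) over all M x N
    window pairs; the diagonal averages over distinct ordered within-session
    pairs.  Outlier-trial bins are excluded by default.  The matrix is
    generally asymmetric; use ``(A + A.T) / 2`` for a symmetric view.
    Sessions with no complete window yield NaN rows/columns.
    """
    check_is_fitted(scorer, "reference_")
    days, summaries = [], []
    for sess in sessions:
        z, z_valid, _ = scorer._prepare(sess)
        der = scorer._derived(sess, z, z_valid)
        valid = der.valid.copy()
        if exclude_outliers:
            valid &= ~sess.outlier_bin_mask()
        grid = window_grid(sess, window_s, step_s)
        sums = []
        for s, e in grid:
            rows = der.values[s:e][valid[s:e]]
            if rows.shape[0] >= scorer.k_ + 2:
                sums.append(gaussian_summary(rows))
        days.append(sess.session_day)
        summaries.append(sums)

    S = len(sessions)
    mat = np.full((S, S), np.nan)
    for i in range(S):
        for j in range(S):
            wi, wj = summaries[i], summaries[j]
            if not wi or not wj:
                continue
            if i == j:
                vals = [
                    gaussian_kld(a, b)
                    for ai, a in enumerate(wi)
                    for bj, b in enumerate(wj)
                    if ai != bj
                ]
            else:
                vals = [gaussian_kld(a, b) for a in wi for b in wj]
            mat[i, j] = float(np.mean(vals)) if vals else np.nan
    return pd.DataFrame(mat, index=days, columns=days)
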