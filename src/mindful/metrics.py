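"""Closed-loop performance ground truth: instantaneous and windowed angle
error, and correlation diagnostics between a drift trace and performance.

Angle error (AE) is the absolute angle between the inferred intended
direction (cursor-to-target vector) and the decoded velocity vector: 0 deg
is best, 180 deg worst.  It is sensitive to instantaneous direction changes
and can be aggregated over any horizon; windowed medians (rather than
means) are used because AE distributions skew toward low values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import BinnedSession

logger = logging.getLogger(__name__)

__all__ = [
    "AngleErrorTrace",
    "angle_error",
    "window_grid",
    "windowed_median_ae",
    "per_trial_median_ae",
    "score_performance_correlation",
    "ranksum_day_groups",
]

_EPS = 1e-12


@dataclass
class AngleErrorTrace:
    """Per-bin angle error in degrees with a validity mask.

    Bins outside any trial, or with a degenerate (zero-norm) intended or
    decoded vector, are masked invalid; their ``ae`` entries are NaN.
    """

    ae: np.ndarray        # (T,) degrees in [0, 180], NaN where invalid
    valid: np.ndarray     # (T,) bool

    def masked(self, extra_exclude: np.ndarray | None = None) -> np.ndarray:
        """Valid mask optionally minus an extra exclusion mask."""
        if extra_exclude is None:
            return self.valid
        return self.valid & ~extra_exclude


def angle_error(session: BinnedSession) -> AngleErrorTrace:
    """Instantaneous AE between intended direction and decoded velocity."""
    d = session.target_pos - session.cursor_pos
    v = session.decoded_velocity
    nd = np.linalg.norm(d, axis=1)
    nv = np.linalg.norm(v, axis=1)
    valid = (nd > _EPS) & (nv > _EPS) & session.trial_mask()
    cos = np.full(session.n_bins, np.nan)
    ok = valid
    cos[ok] = np.einsum("ij,ij->i", d[ok], v[ok]) / (nd[ok] * nv[ok])
    ae = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return AngleErrorTrace(ae=ae, valid=valid)


def window_grid(
    session: BinnedSession, window_s: float = 60.0, step_s: float = 1.0
) -> np.ndarray:
    """Sliding-window bin spans shared by the drift trace and median AE.

    Windows are trailing, anchored at block starts, stepped by ``step_s``
    and never span block boundaries.  Returns an (n_windows, 2) array of
    half-open ``[start_bin, end_bin)`` spans.
    """
    if window_s < step_s:
        raise ValueError("window must be at least one step long")
    W = int(round(window_s / session.bin_width))
    S = max(int(round(step_s / session.bin_width)), 1)
    starts = session.block_starts()
    bounds = list(starts) + [session.n_bins]
    spans = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        s = b0
        while s + W <= b1:
            spans.append((s, s + W))
            s += S
    return np.array(spans, dtype=int).reshape(-1, 2)


def windowed_median_ae(
    trace: AngleErrorTrace,
    grid: np.ndarray,
    min_valid_frac: float = 0.5,
) -> np.ndarray:
    """Median AE per window over valid bins; NaN when <50% of bins are valid.

    Even-count medians use the conventional mean of the two central order
    statistics.  Masked bins never influence the result.
    """
    out = np.full(len(grid), np.nan)
    for i, (s, e) in enumerate(grid):
        m = trace.valid[s:e]
        if m.mean() < min_valid_frac or not m.any():
            continue
        out[i] = np.median(trace.ae[s:e][m])
    return out


def per_trial_median_ae(
    session: BinnedSession, trace: AngleErrorTrace | None = None
) -> tuple[np.ndarray, float, float]:
    """Median AE within each trial span, plus across-trial mean and sample SD.

    Trials with no valid bins are excluded (logged).  Returns
    ``(per_trial, mean, sd)``; SD uses ddof=1 (0.0 for a single trial).
    """
    if trace is None:
        trace = angle_error(session)
    vals = []
    skipped = 0
    for tr in session.trials:
        m = trace.valid[tr.start_bin : tr.end_bin]
        if not m.any():
            skipped += 1
            continue
        vals.append(np.median(trace.ae[tr.start_bin : tr.end_bin][m]))
    if skipped:
        logger.info("per_trial_median_ae: %d trial(s) had no valid bins", skipped)
    per_trial = np.array(vals)
    if per_trial.size == 0:
        return per_trial, np.nan, np.nan
    sd = float(per_trial.std(ddof=1)) if per_trial.size > 1 else 0.0
    return per_trial, float(per_trial.mean()), sd


def score_performance_correlation(
    kld: np.ndarray, med_ae: np.ndarray
) -> tuple[float, float, float, float, int]:
    """Pearson and Spearman correlation between a drift trace and median AE.

    Series must share the window grid; pairs with a missing value in either
    series are dropped listwise.  Returns
    ``(pearson_r, pearson_p, spearman_rho, spearman_p, n)``.
    """
    kld = np.asarray(kld, dtype=float)
    med_ae = np.asarray(med_ae, dtype=float)
    if kld.shape != med_ae.shape:
        raise ValueError("series must share the window grid")
    ok = np.isfinite(kld) & np.isfinite(med_ae)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    pr = stats.pearsonr(kld[ok], med_ae[ok])
    sr = stats.spearmanr(kld[ok], med_ae[ok])
    return float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue), n


def ranksum_day_groups(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison between two day groups."""
    res = stats.ranksums(values_a, values_b)
    return float(res.statistic), float(res.pvalue)
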