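"""Cosine directional tuning and its session-to-session drift.

Each feature's dependence on intended movement direction is modelled as
``y = b0 + b1 cos(theta) + b2 sin(theta)``, equivalently
``y = b0 + MD * cos(theta - PD)`` with modulation depth
``MD = sqrt(b1^2 + b2^2)`` and preferred direction ``PD = atan2(b2, b1)``.
Samples are the z-scored feature values in the first second after the go
cue (offset by a 160 ms reaction time) of non-outlier trials, each bin
labelled with the trial's intended direction.  Tuning is significant when
the regression F-test has p < 0.05.

Session-to-session drift is quantified by ``dMD = MD - MD_ref`` and the
circular ``|dPD| = min(360 - |PD - PD_ref|, |PD - PD_ref|)`` against the
first day the feature was significantly tuned, with trial-level bootstrap
confidence intervals; population-level drift by Pearson correlation of
3 x N tuning maps restricted to features significant on both days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator

from .session import BinnedSession

logger = logging.getLogger(__name__)

__all__ = [
    "TuningSamples",
    "TuningFit",
    "CosineTuning",
    "extract_tuning_samples",
    "fit_cosine",
    "delta_tuning",
    "BootstrapDeltaResult",
    "bootstrap_delta_significance",
    "session_tuning_fits",
    "TuningMap",
    "build_tuning_map",
    "tuning_similarity",
    "tuning_similarity_matrix",
    "cluster_feature_order",
    "correlate_kld_with_similarity",
]

REACTION_TIME_S = 0.160
TUNING_WINDOW_S = 1.0
SIGNIFICANCE_ALPHA = 0.05


@dataclass
class TuningSamples:
    """Per-feature regression sample: direction angle and feature value."""

    theta_deg: np.ndarray
    y: np.ndarray
    trial_id: np.ndarray
    feature_id: int
    session_day: int


@dataclass(frozen=True)
class TuningFit:
    """Fitted cosine tuning curve for one feature on one session."""

    b0: float
    b1: float
    b2: float
    md: float
    pd_deg: float
    f_stat: float
    p_value: float
    n_obs: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA


class CosineTuning(BaseEstimator):
    """OLS cosine-tuning estimator: ``y ~ 1 + cos(theta) + sin(theta)``.

    Fitted attributes: ``b0_``, ``b1_``, ``b2_``, ``md_``, ``pd_deg_``
    (in [0, 360)), ``f_stat_``, ``p_value_`` (overall F with (2, n-3)
    degrees of freedom) and ``n_obs_``.
    """

    def fit(self, theta_deg: np.ndarray, y: np.ndarray) -> "CosineTuning":
        theta_deg = np.asarray(theta_deg, dtype=float)
        y = np.asarray(y, dtype=float)
        n = theta_deg.shape[0]
        if n < 6:
            raise ValueError(f"need at least 6 observations, got {n}")
        if np.unique(np.round(theta_deg % 360.0, 9)).size < 3:
            raise ValueError("need at least 3 distinct direction angles")
        th = np.radians(theta_deg)
        X = np.column_stack([np.ones(n), np.cos(th), np.sin(th)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            raise ValueError("rank-deficient tuning design")
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        ess = max(tss - rss, 0.0)
        df_num, df_den = 2, n - 3
        if rss <= 0:
            f = np.inf
            p = 0.0
        else:
            f = (ess / df_num) / (rss / df_den)
            p = float(stats.f.sf(f, df_num, df_den))
        self.b0_, self.b1_, self.b2_ = map(float, beta)
        self.md_ = float(np.hypot(self.b1_, self.b2_))
        pd_deg = float(np.degrees(np.arctan2(self.b2_, self.b1_)) % 360.0)
        self.pd_deg_ = 0.0 if pd_deg >= 360.0 else pd_deg
        self.f_stat_ = float(f)
        self.p_value_ = p
        self.n_obs_ = n
        return self

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        th = np.radians(np.asarray(theta_deg, dtype=float))
        return self.b0_ + self.b1_ * np.cos(th) + self.b2_ * np.sin(th)

    def to_fit(self) -> TuningFit:
        return TuningFit(
            b0=self.b0_, b1=self.b1_, b2=self.b2_, md=self.md_,
            pd_deg=self.pd_deg_, f_stat=self.f_stat_, p_value=self.p_value_,
            n_obs=self.n_obs_,
        )


def fit_cosine(samples: TuningSamples) -> TuningFit:
    """Least-squares cosine fit of one feature's tuning samples."""
    return CosineTuning().fit(samples.theta_deg, samples.y).to_fit()


def extract_tuning_samples(
    session: BinnedSession,
    zfeatures: np.ndarray,
    reaction_time_s: float = REACTION_TIME_S,
    window_s: float = TUNING_WINDOW_S,
) -> list[TuningSamples]:
    """Tuning samples for every feature: 50 bins/trial in the reach window.

    The window is ``[go_cue + reaction_time, go_cue + reaction_time +
    window_s)``; trials too short for the full window contribute their
    available bins (logged).  Outlier trials contribute nothing.  The
    direction label is the angle of (target - cursor) at the go cue — the
    target direction for centre-out, the inferred intended direction for
    random-target tasks.
    """
    off = int(round(reaction_time_s / session.bin_width))
    span = int(round(window_s / session.bin_width))
    thetas, rows, trial_ids = [], [], []
    truncated = 0
    for tid, tr in enumerate(session.trials):
        if tr.outlier:
            continue
        s = tr.go_cue_bin + off
        e = min(s + span, tr.end_bin)
        if e <= s:
            continue
        if e - s < span:
            truncated += 1
        d = session.target_pos[tr.go_cue_bin] - session.cursor_pos[tr.go_cue_bin]
        theta = float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)
        thetas.append(np.full(e - s, theta))
        rows.append(zfeatures[s:e])
        trial_ids.append(np.full(e - s, tid))
    if truncated:
        logger.info("extract_tuning_samples: %d trial(s) truncated", truncated)
    if not rows:
        theta_all = np.empty(0)
        y_all = np.empty((0, zfeatures.shape[1]))
        tid_all = np.empty(0, dtype=int)
    else:
        theta_all = np.concatenate(thetas)
        y_all = np.concatenate(rows)
        tid_all = np.concatenate(trial_ids)
    return [
        TuningSamples(
            theta_deg=theta_all, y=y_all[:, c], trial_id=tid_all,
            feature_id=c, session_day=session.session_day,
        )
        for c in range(zfeatures.shape[1])
    ]


def delta_tuning(fit: TuningFit, ref: TuningFit) -> tuple[float, float]:
    """(dMD, |dPD|) of a fit against the reference-day fit.

    ``dMD`` is signed; ``|dPD|`` is the circular absolute difference in
    [0, 180].
    """
    dmd = fit.md - ref.md
    raw = abs(fit.pd_deg - ref.pd_deg)
    dpd = min(360.0 - raw, raw)
    return float(dmd), float(dpd)


def _signed_wrap(deg: np.ndarray) -> np.ndarray:
    """Map angle differences to signed values in (-180, 180]."""
    return -((180.0 - np.asarray(deg)) % 360.0 - 180.0)


@dataclass(frozen=True)
class BootstrapDeltaResult:
    """Percentile CIs for the tuning change between two sessions."""

    ci_md: tuple[float, float]
    ci_pd: tuple[float, float]
    significant_md: bool
    significant_pd: bool
    n_boot: int

    @property
    def significant_change(self) -> bool:
        return self.significant_md or self.significant_pd


def _resample_fit(
    samples: TuningSamples, rng: np.random.Generator
) -> tuple[float, float] | None:
    trials = np.unique(samples.trial_id)
    pick = rng.choice(trials, size=trials.size, replace=True)
    idx = np.concatenate([np.flatnonzero(samples.trial_id == t) for t in pick])
    theta, y = samples.theta_deg[idx], samples.y[idx]
    if np.unique(np.round(theta % 360.0, 9)).size < 3:
        return None
    m = CosineTuning().fit(theta, y)
    return m.md_, m.pd_deg_


def bootstrap_delta_significance(
    samples_a: TuningSamples,
    samples_b: TuningSamples,
    B: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> BootstrapDeltaResult:
    """Trial-level bootstrap test for a change in MD or PD between sessions.

    Trials (not bins) are resampled with replacement within each session to
    respect within-trial correlation; each resample is refit and paired
    differences ``MD_b - MD_a`` and the signed wrapped ``PD_b - PD_a`` (in
    (-180, 180]) are collected.  A change is significant when the
    ``level`` percentile CI of its difference distribution excludes 0.
    Rank-deficient resamples are redrawn (capped at 10*B redraws).
    """
    rng = np.random.default_rng(rng)
    d_md = np.empty(B)
    d_pd = np.empty(B)
    draws = 0
    b = 0
    while b < B:
        if draws > 10 * B:
            raise RuntimeError("too many rank-deficient bootstrap resamples")
        draws += 1
        fa = _resample_fit(samples_a, rng)
        fb = _resample_fit(samples_b, rng)
        if fa is None or fb is None:
            continue
        d_md[b] = fb[0] - fa[0]
        d_pd[b] = _signed_wrap(fb[1] - fa[1])
        b += 1
    alpha = 1.0 - level
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_md = tuple(np.percentile(d_md, [lo, hi]))
    ci_pd = tuple(np.percentile(d_pd, [lo, hi]))
    return BootstrapDeltaResult(
        ci_md=(float(ci_md[0]), float(ci_md[1])),
        ci_pd=(float(ci_pd[0]), float(ci_pd[1])),
        significant_md=not (ci_md[0] <= 0.0 <= ci_md[1]),
        significant_pd=not (ci_pd[0] <= 0.0 <= ci_pd[1]),
        n_boot=B,
    )


def session_tuning_fits(
    session: BinnedSession, zfeatures: np.ndarray
) -> pd.DataFrame:
    """Cosine fits for every feature of one session.

    Columns: feature_id, b0, b1, b2, md, pd, f, p, significant, n_obs.
    Features whose fit fails (too few trials, degenerate design) get NaN
    coefficients and significant=False.
    """
    recs = []
    for smp in extract_tuning_samples(session, zfeatures):
        try:
            fit = fit_cosine(smp)
            recs.append(
                {
                    "feature_id": smp.feature_id, "b0": fit.b0, "b1": fit.b1,
                    "b2": fit.b2, "md": fit.md, "pd": fit.pd_deg,
                    "f": fit.f_stat, "p": fit.p_value,
                    "significant": fit.significant, "n_obs": fit.n_obs,
                }
            )
        except ValueError:
            recs.append(
                {
                    "feature_id": smp.feature_id, "b0": np.nan, "b1": np.nan,
                    "b2": np.nan, "md": np.nan, "pd": np.nan, "f": np.nan,
                    "p": np.nan, "significant": False, "n_obs": len(smp.y),
                }
            )
    df = pd.DataFrame(recs)
    df["session_day"] = session.session_day
    return df


@dataclass
class TuningMap:
    """3 x N matrix of (b0, b1, b2) for the session's significant features."""

    session_day: int
    feature_ids: np.ndarray
    params: np.ndarray  # (3, N)


def build_tuning_map(fits: pd.DataFrame) -> TuningMap:
    """Tuning map of one session from its per-feature fit table."""
    sig = fits[fits["significant"]].sort_values("feature_id")
    if sig.empty:
        logger.info("build_tuning_map: no significant features")
    return TuningMap(
        session_day=int(fits["session_day"].iloc[0]) if len(fits) else -1,
        feature_ids=sig["feature_id"].to_numpy(int),
        params=sig[["b0", "b1", "b2"]].to_numpy(float).T,
    )


def tuning_similarity(map_i: TuningMap, map_j: TuningMap) -> float:
    """Pearson r between two tuning maps over features significant in both.

    Returns NaN when fewer than 2 shared features exist.
    """
    shared, ia, ja = np.intersect1d(
        map_i.feature_ids, map_j.feature_ids, return_indices=True
    )
    if shared.size < 2:
        return np.nan
    a = map_i.params[:, ia].ravel()
    b = map_j.params[:, ja].ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def tuning_similarity_matrix(maps: list[TuningMap]) -> pd.DataFrame:
    """Symmetric S x S matrix of pairwise tuning-map correlations."""
    days = [m.session_day for m in maps]
    S = len(maps)
    out = np.full((S, S), np.nan)
    for i in range(S):
        for j in range(i, S):
            r = 1.0 if i == j else tuning_similarity(maps[i], maps[j])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=days, columns=days)


def cluster_feature_order(
    delta_md: pd.DataFrame, delta_pd: pd.DataFrame
) -> np.ndarray:
    """Dendrogram leaf order grouping features with similar drift profiles.

    Rows of the inputs are sessions, columns features (NaN where the feature
    was not significantly tuned that session).  Each measure is standardized
    over its observed entries, NaNs are imputed at the standardized mean
    (0), each feature's sessions-long dMD and dPD profiles are concatenated,
    and Ward-linkage hierarchical clustering on Euclidean distances supplies
    the leaf order (a permutation of the retained columns; columns with no
    observations at all are dropped).
    """
    if not delta_md.columns.equals(delta_pd.columns):
        raise ValueError("delta matrices must share feature columns")
    keep = delta_md.notna().any(axis=0) | delta_pd.notna().any(axis=0)
    md = delta_md.loc[:, keep]
    pdm = delta_pd.loc[:, keep]
    if md.shape[1] == 1:
        return np.array([0])

    def _std(df: pd.DataFrame) -> np.ndarray:
        arr = df.to_numpy(float)
        mu = np.nanmean(arr)
        sd = np.nanstd(arr)
        arr = (arr - mu) / (sd if sd > 0 else 1.0)
        return np.nan_to_num(arr, nan=0.0)

    profile = np.vstack([_std(md), _std(pdm)]).T  # (F, 2S)
    Z = linkage(profile, method="ward", metric="euclidean")
    return np.asarray(leaves_list(Z))


def correlate_kld_with_similarity(
    mean_kld: pd.DataFrame, similarity: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between inter-session mean KLD and tuning similarity.

    Uses upper-triangle off-diagonal session pairs where both matrices are
    observed; matrices must share session ordering.
    """
    if mean_kld.shape != similarity.shape:
        raise ValueError("matrices must share shape and session ordering")
    S = mean_kld.shape[0]
    iu = np.triu_indices(S, k=1)
    a = mean_kld.to_numpy(float)[iu]
    b = similarity.to_numpy(float)[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete session pairs")
    res = stats.pearsonr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)
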