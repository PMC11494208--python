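"""Session data model for binned closed-loop cursor-BCI recordings.

A :class:`BinnedSession` holds everything one research session produces at
20 ms resolution: the per-channel neural feature matrix (threshold-crossing
rates and/or spike-band power), the decoded 2-D velocity, cursor and active
target positions, block identifiers and a trial table.  Sessions are stored
on disk as a directory of plain columnar tables (``meta.json``,
``bins.csv``/``bins.parquet``, ``trials.csv``) so they stay diffable and
readable from any language.

Conventions
-----------
Coordinates are screen units, y-up, origin at screen centre.  Bins are
half-open ``[t, t + bin_width)``; trial spans are half-open in bin indices.
``target_pos`` carries the active target forward through inter-trial gaps;
bins outside any trial are excluded from performance aggregation downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "BinnedSession",
    "read_session",
    "write_session",
    "flag_outlier_trials",
]


class SessionFormatError(ValueError):
    """On-disk session does not conform to the documented schema."""


class SessionIntegrityError(ValueError):
    """Session arrays violate a structural invariant (e.g. length mismatch)."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial: half-open bin span, go cue, target and quality flags."""

    start_bin: int
    go_cue_bin: int
    end_bin: int
    target: np.ndarray  # shape (2,)
    success: bool
    packet_drop_frac: float = 0.0
    outlier: bool = False

    def __post_init__(self) -> None:
        if not (self.start_bin <= self.go_cue_bin < self.end_bin):
            raise SessionIntegrityError(
                f"trial span invalid: start={self.start_bin}, "
                f"go_cue={self.go_cue_bin}, end={self.end_bin}"
            )
        if not (0.0 <= self.packet_drop_frac <= 1.0):
            raise SessionIntegrityError(
                f"packet_drop_frac {self.packet_drop_frac} outside [0, 1]"
            )
        object.__setattr__(
            self, "target", np.asarray(self.target, dtype=float).reshape(2)
        )

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class BinnedSession:
    """One recording session of binned neural features and cursor kinematics.

    Parameters
    ----------
    session_day : int
        Days since the decoder was first deployed (day 0).
    features : ndarray of shape (T, C)
        Neural features per bin (counts/bin or band power), float64.
    decoded_velocity : ndarray of shape (T, 2)
        Decoder output per bin (screen units / s).
    cursor_pos, target_pos : ndarray of shape (T, 2)
        Cursor and active-target position per bin.
    block_id : ndarray of shape (T,)
        Non-decreasing task-block identifier per bin.
    trials : sequence of TrialRecord
        Ordered, disjoint trial spans within ``[0, T)``.
    bin_width : float
        Bin width in seconds (0.020 throughout this package).
    """

    session_day: int
    features: np.ndarray
    decoded_velocity: np.ndarray
    cursor_pos: np.ndarray
    target_pos: np.ndarray
    block_id: np.ndarray
    trials: Sequence[TrialRecord] = field(default_factory=list)
    bin_width: float = 0.020
    participant: str = "sim"
    decoder: str = "sim-linear"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.decoded_velocity = np.asarray(self.decoded_velocity, dtype=float)
        self.cursor_pos = np.asarray(self.cursor_pos, dtype=float)
        self.target_pos = np.asarray(self.target_pos, dtype=float)
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.trials = list(self.trials)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def block_starts(self) -> np.ndarray:
        """Bin indices where a new block begins (always includes 0)."""
        if self.n_bins == 0:
            return np.array([], dtype=int)
        change = np.flatnonzero(np.diff(self.block_id)) + 1
        return np.concatenate(([0], change))

    def trial_mask(self) -> np.ndarray:
        """Boolean mask of bins that fall inside any trial span."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for tr in self.trials:
            mask[tr.start_bin : tr.end_bin] = True
        return mask

    def outlier_bin_mask(self) -> np.ndarray:
        """Boolean mask of bins inside outlier-flagged trials."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for tr in self.trials:
            if tr.outlier:
                mask[tr.start_bin : tr.end_bin] = True
        return mask

    def validate(self) -> None:
        """Raise SessionIntegrityError on any invariant violation."""
        T = self.features.shape[0]
        if self.features.ndim != 2:
            raise SessionIntegrityError("features must be 2-D (T x C)")
        for name in ("decoded_velocity", "cursor_pos", "target_pos"):
            arr = getattr(self, name)
            if arr.shape != (T, 2):
                raise SessionIntegrityError(
                    f"{name} has shape {arr.shape}, expected ({T}, 2)"
                )
        if self.block_id.shape != (T,):
            raise SessionIntegrityError(
                f"block_id has shape {self.block_id.shape}, expected ({T},)"
            )
        if self.bin_width <= 0:
            raise SessionIntegrityError("bin_width must be positive")
        if T and np.any(np.diff(self.block_id) < 0):
            raise SessionIntegrityError("block_id must be non-decreasing")
        prev_end = 0
        for i, tr in enumerate(self.trials):
            if tr.start_bin < prev_end:
                raise SessionIntegrityError(
                    f"trial {i} overlaps or precedes trial {i - 1}"
                )
            if tr.end_bin > T:
                raise SessionIntegrityError(f"trial {i} extends past T={T}")
            prev_end = tr.end_bin

    def copy(self) -> "BinnedSession":
        return BinnedSession(
            session_day=self.session_day,
            features=self.features.copy(),
            decoded_velocity=self.decoded_velocity.copy(),
            cursor_pos=self.cursor_pos.copy(),
            target_pos=self.target_pos.copy(),
            block_id=self.block_id.copy(),
            trials=[replace(t) for t in self.trials],
            bin_width=self.bin_width,
            participant=self.participant,
            decoder=self.decoder,
        )


# ----------------------------------------------------------------------
# On-disk schema
# ----------------------------------------------------------------------

_TRIAL_COLS = [
    "start_bin",
    "go_cue_bin",
    "end_bin",
    "target_x",
    "target_y",
    "success",
    "packet_drop_frac",
    "outlier",
]


def write_session(session: BinnedSession, path: str | Path, *, fmt: str = "csv") -> None:
    """Write a session as a directory of ``meta.json`` + columnar tables.

    ``fmt`` selects ``bins.csv`` (default, diffable) or ``bins.parquet``.
    Numeric values survive a round trip at full float64 precision (CSV uses
    repr-exact formatting).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_day": int(session.session_day),
        "bin_width": float(session.bin_width),
        "participant": session.participant,
        "decoder": session.decoder,
        "n_channels": int(session.n_channels),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))

    C = session.n_channels
    bins = pd.DataFrame({"bin_index": np.arange(session.n_bins)})
    bins["block_id"] = session.block_id
    for c in range(C):
        bins[f"feat_{c:03d}"] = session.features[:, c]
    bins["vx_hat"], bins["vy_hat"] = session.decoded_velocity.T
    bins["cursor_x"], bins["cursor_y"] = session.cursor_pos.T
    bins["target_x"], bins["target_y"] = session.target_pos.T

    if fmt == "parquet":
        bins.to_parquet(path / "bins.parquet", index=False)
    elif fmt == "csv":
        # float_format=None + repr round-trips float64 exactly
        bins.to_csv(path / "bins.csv", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown session format {fmt!r}")

    trials = pd.DataFrame(
        [
            {
                "start_bin": t.start_bin,
                "go_cue_bin": t.go_cue_bin,
                "end_bin": t.end_bin,
                "target_x": t.target[0],
                "target_y": t.target[1],
                "success": int(t.success),
                "packet_drop_frac": t.packet_drop_frac,
                "outlier": int(t.outlier),
            }
            for t in session.trials
        ],
        columns=_TRIAL_COLS,
    )
    trials.to_csv(path / "trials.csv", index=False, float_format="%.17g")


def read_session(path: str | Path) -> BinnedSession:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionFormatError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("session_day", "bin_width"):
        if key not in meta:
            raise SessionFormatError(f"meta.json missing field {key!r}")

    if (path / "bins.parquet").exists():
        bins = pd.read_parquet(path / "bins.parquet")
    elif (path / "bins.csv").exists():
        bins = pd.read_csv(path / "bins.csv", float_precision="round_trip")
    else:
        raise SessionFormatError(f"missing bins table in {path}")

    feat_cols = sorted(c for c in bins.columns if c.startswith("feat_"))
    required = ["block_id", "vx_hat", "vy_hat", "cursor_x", "cursor_y",
                "target_x", "target_y"]
    for col in required:
        if col not in bins.columns:
            raise SessionFormatError(f"bins table missing column {col!r}")
    if not feat_cols:
        raise SessionFormatError("bins table has no feat_* columns")

    trials_path = path / "trials.csv"
    if not trials_path.exists():
        raise SessionFormatError(f"missing trials.csv in {path}")
    tdf = pd.read_csv(trials_path, float_precision="round_trip")
    for col in _TRIAL_COLS:
        if col not in tdf.columns and len(tdf):
            raise SessionFormatError(f"trials.csv missing column {col!r}")
    trials = [
        TrialRecord(
            start_bin=int(r.start_bin),
            go_cue_bin=int(r.go_cue_bin),
            end_bin=int(r.end_bin),
            target=np.array([r.target_x, r.target_y]),
            success=bool(r.success),
            packet_drop_frac=float(r.packet_drop_frac),
            outlier=bool(r.outlier),
        )
        for r in tdf.itertuples()
    ]

    return BinnedSession(
        session_day=int(meta["session_day"]),
        features=bins[feat_cols].to_numpy(float),
        decoded_velocity=bins[["vx_hat", "vy_hat"]].to_numpy(float),
        cursor_pos=bins[["cursor_x", "cursor_y"]].to_numpy(float),
        target_pos=bins[["target_x", "target_y"]].to_numpy(float),
        block_id=bins["block_id"].to_numpy(int),
        trials=trials,
        bin_width=float(meta["bin_width"]),
        participant=str(meta.get("participant", "unknown")),
        decoder=str(meta.get("decoder", "unknown")),
    )


# ----------------------------------------------------------------------
# Outlier-trial flagging
# ----------------------------------------------------------------------

def flag_outlier_trials(
    session: BinnedSession,
    drop_thresh: float = 0.05,
    amp_sd: float = 8.0,
) -> int:
    """Flag trials with heavy packet loss or extreme amplitude excursions.

    A trial is an outlier when its wireless packet-drop fraction exceeds
    ``drop_thresh`` (default 5%), or when any bin inside the trial carries a
    channel value more than ``amp_sd`` standard deviations (default 8) above
    that channel's session mean.  Channel statistics are computed over the
    whole session excluding bins that already sit inside packet-drop-flagged
    trials, so a transmission glitch does not inflate the amplitude baseline.
    Flags are written in place; the number of flagged trials is returned.

    Idempotent, and monotone in ``amp_sd``: a lower threshold flags a
    superset of trials.
    """
    if session.features.size == 0:
        raise ValueError("session has no feature bins")

    drop_flags = [t.packet_drop_frac > drop_thresh for t in session.trials]

    stat_mask = np.ones(session.n_bins, dtype=bool)
    for t, dropped in zip(session.trials, drop_flags):
        if dropped:
            stat_mask[t.start_bin : t.end_bin] = False
    base = session.features[stat_mask] if stat_mask.any() else session.features
    mu = base.mean(axis=0)
    sd = base.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning(
            "flag_outlier_trials: %d zero-variance channel(s) skipped in "
            "amplitude test", int(dead.sum())
        )
    thresh = mu + amp_sd * sd
    thresh[dead] = np.inf

    n_flagged = 0
    new_trials = []
    for t, dropped in zip(session.trials, drop_flags):
        seg = session.features[t.start_bin : t.end_bin]
        amp_hit = bool((seg > thresh).any()) if seg.size else False
        is_out = bool(dropped or amp_hit)
        new_trials.append(replace(t, outlier=is_out))
        n_flagged += is_out
    session.trials = new_trials
    return n_flagged
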