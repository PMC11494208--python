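"""Synthetic multi-session closed-loop cursor-BCI studies with known drift.

The generator emulates the study conditions every analysis stage needs:
cosine-tuned multi-channel count features at 20 ms resolution, a fixed
linear velocity decoder with exponential output smoothing (and optional
running bias correction), centre-out-and-back and random-target trial
structure, and session-to-session drift — preferred-direction rotation
(global or per-channel), modulation-depth scaling, baseline shifts, channel
dropout and injected packet-drop / amplitude outlier events.

Channel rates follow a rectified-linear cosine law,
``r_c = max(0, baseline_c + md_c * cos(theta - pd_c))``, matching the
cosine regression the analysis fits so planted parameters are directly
recoverable.  Counts are Poisson (or Gaussian) draws at each 20 ms bin;
the decoder normalizes them with statistics frozen at calibration and can
subtract a running output-bias estimate, while the drift analysis applies
its own causal rolling z-score to the recorded counts.  The decoded
velocity is exponentially smoothed,
``Xhat_t = alpha * Xhat_{t-1} + (1 - alpha) * beta * v_t``.

Everything is deterministic under a seed; ``generate_study`` also returns a
ground-truth table of per-session drift magnitudes for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .session import BinnedSession, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "SimDecoder",
    "DriftEntry",
    "DriftSchedule",
    "simulate_session",
    "train_sim_decoder",
    "generate_study",
    "graded_drift_schedule",
    "stationary_schedule",
]

BIN_WIDTH_S = 0.020
REACTION_BINS = 8          # 160 ms
TIMEOUT_S = 10.0
DWELL_S = 0.5              # random-target acquisition dwell
TARGET_RADIUS = 0.07
RING_RADIUS = 0.38         # centre-out target ring
WORKSPACE_HALF = 0.55
SPEED_CAP = 1.0            # screen units / s


@dataclass
class PopulationSpec:
    """Cosine-tuned channel population: baseline, modulation, preferred dirs."""

    baseline_hz: np.ndarray
    md_hz: np.ndarray
    pd_deg: np.ndarray
    noise: str = "poisson"        # "poisson" | "gaussian"
    gaussian_sd: float = 0.5      # count-units, used when noise == "gaussian"

    def __post_init__(self) -> None:
        self.baseline_hz = np.asarray(self.baseline_hz, dtype=float)
        self.md_hz = np.asarray(self.md_hz, dtype=float)
        self.pd_deg = np.asarray(self.pd_deg, dtype=float)
        if np.any(self.baseline_hz < 0):
            raise ValueError("baseline rates must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.baseline_hz.shape[0]

    @classmethod
    def random(
        cls,
        n_channels: int = 24,
        rng: np.random.Generator | int | None = None,
        baseline_range: tuple[float, float] = (40.0, 80.0),
        md_range: tuple[float, float] = (11.0, 23.0),
        noise: str = "poisson",
    ) -> "PopulationSpec":
        """Population with uniform-random baselines/MDs and evenly spread PDs."""
        rng = np.random.default_rng(rng)
        pd_deg = (
            np.linspace(0.0, 360.0, n_channels, endpoint=False)
            + rng.uniform(-10, 10, n_channels)
        ) % 360.0
        return cls(
            baseline_hz=rng.uniform(*baseline_range, n_channels),
            md_hz=rng.uniform(*md_range, n_channels),
            pd_deg=pd_deg,
            noise=noise,
        )


@dataclass
class SimDecoder:
    """Fixed linear velocity decoder with exponential output smoothing.

    Incoming counts are normalized with the *frozen* calibration statistics
    ``feat_mean``/``feat_sd`` (the decoder is fixed; adapting its input
    normalization online would let the normalizer and the task occupancy
    couple); ``weights`` maps the normalized features to the raw velocity
    ``v_t``, and the emitted velocity is
    ``Xhat_t = alpha Xhat_{t-1} + (1-alpha) beta v_t``.  ``bias_adaptation``
    (1/s) enables a running-mean bias subtraction on ``v_t`` that
    counteracts slow output bias from feature mean drift (None = off).
    """

    weights: np.ndarray            # (2, C)
    feat_mean: np.ndarray          # (C,) frozen calibration means
    feat_sd: np.ndarray            # (C,) frozen calibration SDs
    alpha: float = 0.92
    beta: float = 0.35
    bias_adaptation: float | None = 0.3

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feat_mean = np.asarray(self.feat_mean, dtype=float)
        self.feat_sd = np.asarray(self.feat_sd, dtype=float)
        if np.any(self.feat_sd <= 0):
            raise ValueError("feat_sd must be positive")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def normalize(self, counts: np.ndarray) -> np.ndarray:
        return (counts - self.feat_mean) / self.feat_sd


@dataclass
class DriftEntry:
    """Ground-truth drift applied to one session.

    ``pd_rotation_deg`` and ``md_scale`` may be scalars (global) or
    per-channel arrays; ``mean_offset_hz`` shifts baselines; channels in
    ``dropped_channels`` lose their modulation and emit baseline-only
    activity; ``outlier_events`` is a list of ``(trial_index, kind, value)``
    with kind ``"packet_drop"`` (value = drop fraction) or ``"amplitude"``
    (value = excursion size in SDs).
    """

    pd_rotation_deg: float | np.ndarray = 0.0
    md_scale: float | np.ndarray = 1.0
    mean_offset_hz: float | np.ndarray = 0.0
    dropped_channels: frozenset[int] = field(default_factory=frozenset)
    outlier_events: tuple[tuple[int, str, float], ...] = ()

    def apply(self, pop: PopulationSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Drifted (baseline, md, pd) arrays."""
        base = pop.baseline_hz + np.broadcast_to(
            np.asarray(self.mean_offset_hz, dtype=float), (pop.n_channels,)
        )
        md = pop.md_hz * np.broadcast_to(
            np.asarray(self.md_scale, dtype=float), (pop.n_channels,)
        )
        pdd = pop.pd_deg + np.broadcast_to(
            np.asarray(self.pd_rotation_deg, dtype=float), (pop.n_channels,)
        )
        if self.dropped_channels:
            md = md.copy()
            md[list(self.dropped_channels)] = 0.0
        return np.maximum(base, 0.0), md, pdd

    def magnitude(self) -> float:
        """Scalar drift size: mean |PD rotation| in degrees."""
        return float(np.mean(np.abs(self.pd_rotation_deg)))


@dataclass
class DriftSchedule:
    """Per-session drift entries keyed by session day."""

    days: tuple[int, ...]
    entries: tuple[DriftEntry, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.entries):
            raise ValueError("days and entries must align")

    def __len__(self) -> int:
        return len(self.days)


def stationary_schedule(days: Sequence[int]) -> DriftSchedule:
    """All-zero drift: every session drawn from the day-0 population."""
    return DriftSchedule(
        days=tuple(int(d) for d in days),
        entries=tuple(DriftEntry() for _ in days),
    )


def graded_drift_schedule(
    days: Sequence[int],
    max_rotation_deg: float = 90.0,
    n_channels: int = 24,
    per_channel: bool = True,
    md_scale_end: float = 0.7,
    rng: np.random.Generator | int | None = None,
) -> DriftSchedule:
    """Linearly increasing tuning drift across sessions.

    Session ``s`` of ``S`` rotates preferred directions by
    ``(s / (S-1)) * max_rotation_deg``; with ``per_channel`` each channel
    rotates by its own fixed signed fraction of that magnitude (drawn once,
    |fraction| in [0.5, 1]), which changes the direction-coding subspace —
    a uniform global rotation would leave it (and the latent VAF)
    untouched.  Modulation depths shrink linearly to ``md_scale_end``.
    """
    rng = np.random.default_rng(rng)
    S = len(days)
    if per_channel:
        signature = rng.uniform(0.5, 1.0, n_channels) * rng.choice(
            [-1.0, 1.0], n_channels
        )
    else:
        signature = 1.0
    entries = []
    for s in range(S):
        frac = s / (S - 1) if S > 1 else 0.0
        entries.append(
            DriftEntry(
                pd_rotation_deg=frac * max_rotation_deg * signature,
                md_scale=1.0 + frac * (md_scale_end - 1.0),
            )
        )
    return DriftSchedule(days=tuple(int(d) for d in days), entries=tuple(entries))


# ----------------------------------------------------------------------
# Closed-loop simulation
# ----------------------------------------------------------------------

def _center_out_targets(rng: np.random.Generator, n_trials: int) -> list[np.ndarray]:
    """Alternating peripheral/centre targets, peripherals pseudo-random."""
    ring = [
        RING_RADIUS * np.array([np.cos(a), np.sin(a)])
        for a in np.radians(np.arange(0, 360, 45))
    ]
    targets = []
    order: list[int] = []
    for i in range(n_trials):
        if i % 2 == 0:
            if not order:
                order = list(rng.permutation(8))
            targets.append(ring[order.pop()])
        else:
            targets.append(np.zeros(2))
    return targets


def simulate_session(
    pop: PopulationSpec,
    dec: SimDecoder | None,
    task: str = "center_out_back",
    n_trials: int = 40,
    drift: DriftEntry | None = None,
    rng: np.random.Generator | int | None = None,
    session_day: int = 0,
    open_loop: bool = False,
    open_loop_speed: float = 0.25,
) -> BinnedSession:
    """Run one closed-loop (or open-loop calibration) session.

    Per 20 ms bin: the intended direction is the unit vector from cursor to
    target (held at the pre-go-cue intent for the first 160 ms of each
    trial); drifted channel rates follow the rectified cosine law; counts
    are drawn from the noise model; the decoder normalizes them with its
    frozen calibration statistics and maps them to a raw velocity
    (optionally bias-corrected) which is smoothed and integrated
    into the cursor (speed-capped, clipped to the workspace).  A trial ends
    on target acquisition — entry for centre-out, a consecutive 500 ms
    dwell for random targets — or a 10 s timeout (failure).

    With ``open_loop=True`` the cursor instead moves along the intended
    direction at ``open_loop_speed`` and that velocity is recorded as the
    decoded output; used to create decoder-training data.
    """
    if task not in ("center_out_back", "random_target"):
        raise ValueError(f"unknown task {task!r}")
    if dec is None and not open_loop:
        raise ValueError("closed-loop simulation requires a decoder")
    rng = np.random.default_rng(rng)
    drift = drift or DriftEntry()
    base, md, pdd = drift.apply(pop)
    pd_rad = np.radians(pdd)
    dt = BIN_WIDTH_S
    C = pop.n_channels
    timeout_bins = int(round(TIMEOUT_S / dt))
    dwell_bins = int(round(DWELL_S / dt))

    events = {t: (kind, val) for t, kind, val in drift.outlier_events}

    if task == "center_out_back":
        targets = _center_out_targets(rng, n_trials)
    else:
        targets = [
            rng.uniform(-0.4, 0.4, 2) for _ in range(n_trials)
        ]

    feats, vels, curs, targs, blocks = [], [], [], [], []
    trials: list[TrialRecord] = []
    cursor = np.zeros(2)
    xhat = np.zeros(2)
    bias = np.zeros(2)
    intent_dir = np.array([1.0, 0.0])  # held intent during reaction time
    t_global = 0

    for trial_idx, target in enumerate(targets):
        start_bin = t_global
        go_cue_bin = t_global
        held_dir = intent_dir.copy()
        dwell = 0
        success = False
        dropped_bins = 0
        event = events.get(trial_idx)
        drop_frac_target = event[1] if event and event[0] == "packet_drop" else 0.0
        amp_event = event if event and event[0] == "amplitude" else None

        for i in range(timeout_bins):
            d = target - cursor
            dist = float(np.linalg.norm(d))
            if i < REACTION_BINS:
                direction = held_dir
            elif dist > 1e-9:
                direction = d / dist
                intent_dir = direction
            else:
                direction = np.zeros(2)

            if np.any(direction):
                theta = np.arctan2(direction[1], direction[0])
                rates = np.maximum(base + md * np.cos(theta - pd_rad), 0.0)
            else:
                rates = base
            lam = rates * dt
            if pop.noise == "poisson":
                counts = rng.poisson(lam).astype(float)
            else:
                counts = lam + pop.gaussian_sd * rng.standard_normal(C)

            in_trial_bins = i + 1
            if drop_frac_target > 0 and dropped_bins < drop_frac_target * in_trial_bins:
                counts = np.zeros(C)
                dropped_bins += 1
            if amp_event is not None and i == REACTION_BINS + 10:
                ch = trial_idx % C
                counts[ch] = lam[ch] + amp_event[1] * max(np.sqrt(lam[ch]), 1.0)

            if open_loop:
                xhat = open_loop_speed * direction
            else:
                v = dec.weights @ dec.normalize(counts)
                if dec.bias_adaptation is not None:
                    g = dec.bias_adaptation * dt
                    bias = (1.0 - g) * bias + g * v
                    v = v - bias
                xhat = dec.alpha * xhat + (1.0 - dec.alpha) * dec.beta * v
                speed = float(np.linalg.norm(xhat))
                if speed > SPEED_CAP:
                    xhat = xhat * (SPEED_CAP / speed)

            feats.append(counts)
            vels.append(xhat.copy())
            curs.append(cursor.copy())
            targs.append(target.copy())
            blocks.append(0)
            t_global += 1

            cursor = np.clip(cursor + xhat * dt, -WORKSPACE_HALF, WORKSPACE_HALF)

            if dist <= TARGET_RADIUS:
                dwell += 1
            else:
                dwell = 0
            need = dwell_bins if task == "random_target" else 1
            if dwell >= need:
                success = True
                break

        n_bins_trial = t_global - start_bin
        frac = dropped_bins / n_bins_trial if n_bins_trial else 0.0
        trials.append(
            TrialRecord(
                start_bin=start_bin,
                go_cue_bin=go_cue_bin,
                end_bin=t_global,
                target=target,
                success=success,
                packet_drop_frac=frac,
            )
        )

    return BinnedSession(
        session_day=session_day,
        features=np.array(feats),
        decoded_velocity=np.array(vels),
        cursor_pos=np.array(curs),
        target_pos=np.array(targs),
        block_id=np.array(blocks, dtype=int),
        trials=trials,
        bin_width=dt,
    )


def train_sim_decoder(
    day0_session: BinnedSession,
    alpha: float = 0.92,
    beta: float = 0.35,
    bias_adaptation: float | None = 0.3,
) -> SimDecoder:
    """Least-squares map from normalized features to intended unit direction.

    Channel means and SDs computed over the calibration session are frozen
    into the decoder as its input normalization.  A singular design falls
    back to a small ridge (logged).  Deterministic: retraining on identical
    data yields identical weights.
    """
    feats = day0_session.features
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (feats - mu) / sd
    d = day0_session.target_pos - day0_session.cursor_pos
    norm = np.linalg.norm(d, axis=1)
    ok = (norm > 1e-9) & day0_session.trial_mask()
    if ok.sum() < z.shape[1] + 2:
        raise ValueError("not enough valid bins to train the decoder")
    X = z[ok]
    Y = d[ok] / norm[ok, None]
    gram = X.T @ X
    try:
        W = np.linalg.solve(gram, X.T @ Y).T
    except np.linalg.LinAlgError:
        logger.warning("train_sim_decoder: singular design, ridge fallback")
        ridge = 1e-6 * np.trace(gram) / gram.shape[0]
        W = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), X.T @ Y).T
    return SimDecoder(weights=W, feat_mean=mu, feat_sd=sd, alpha=alpha,
                      beta=beta, bias_adaptation=bias_adaptation)


def generate_study(
    pop: PopulationSpec,
    schedule: DriftSchedule,
    trials_per_session: int = 120,
    seed: int = 0,
    task: str = "center_out_back",
    alpha: float = 0.92,
    beta: float = 0.35,
    calibration_trials: int = 120,
    dec: SimDecoder | None = None,
) -> tuple[list[BinnedSession], pd.DataFrame, SimDecoder]:
    """Simulate a multi-session study under a drift schedule.

    An open-loop calibration run on day 0 trains the fixed decoder (unless
    one is supplied), which then drives every closed-loop session; each
    session applies its schedule entry.  Deterministic under ``(seed,
    parameters)``; sessions are statistically independent given the
    schedule.  Returns the sessions, a ground-truth table of per-session
    drift magnitudes, and the decoder.
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(schedule) + 1)
    if dec is None:
        calib = simulate_session(
            pop, None, task="center_out_back", n_trials=calibration_trials,
            rng=np.random.default_rng(streams[0]), open_loop=True,
        )
        dec = train_sim_decoder(calib, alpha=alpha, beta=beta)

    sessions = []
    truth = []
    for i, (day, entry) in enumerate(zip(schedule.days, schedule.entries)):
        sess = simulate_session(
            pop, dec, task=task, n_trials=trials_per_session, drift=entry,
            rng=np.random.default_rng(streams[i + 1]), session_day=day,
        )
        sessions.append(sess)
        truth.append(
            {
                "session_day": day,
                "pd_rotation_mean_abs_deg": entry.magnitude(),
                "md_scale_mean": float(np.mean(entry.md_scale)),
                "n_dropped_channels": len(entry.dropped_channels),
                "n_outlier_events": len(entry.outlier_events),
            }
        )
    return sessions, pd.DataFrame(truth), dec
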