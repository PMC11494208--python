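# Methods

## The drift score

The score treats drift detection as a distribution-comparison problem.
Let x_t ∈ ℝᵏ be the derived neural feature vector at 20 ms bin t.  A
reference collection of bins (captured when closed-loop control was known
to be good) and each sliding comparison window are reduced to their first
two moments, (μ₁, Σ₁) and (μ₂, Σ₂), and compared with the closed-form KL
divergence between the corresponding multivariate normals.  The Gaussian
form is a modelling convenience, not an assumption about the data: the
statistic is a moment-based score and remains meaningful for non-Gaussian
features.

Direction matters.  The default evaluates d_KL(reference ‖ window), so the
*comparison window's* covariance is inverted; a window whose covariance
collapses (e.g. near-constant decoder output during a control failure)
inflates the score sharply.  The opposite direction is available via
`MindfulScorer(direction="window_vs_ref")` because the asymmetry is
material when window covariances shrink.

Numerical path: covariances are factorized by Cholesky; traces and
quadratic forms come from triangular solves and log-determinants from
factor diagonals.  Explicit inverses and determinants are never formed.
Sample covariances use the unbiased (n−1) estimator; if a covariance is
ill-conditioned (condition number > 1e8) or under-sampled (n ≤ k), a ridge
of r·tr(Σ)/k escalates from r = 1e-8 by factors of 10 until the factorization
succeeds, and the total ridge is recorded on the summary.  Windows with
fewer than k+2 valid bins emit a missing value rather than a regularized
guess; correlation diagnostics drop missing pairs listwise.

## Derived features

Channel features are standardized causally: each bin is z-scored with the
mean and variance of the trailing 3-min window ending at that bin,
restarting at block boundaries.  For the first 3 min of a block the window
expands from the block start; bins whose expanding window is shorter than
30 s are flagged and excluded from reference and comparison windows (a
trailing-causal rule is used offline as online, so scores computed after
the fact match what a real-time implementation would have seen).
Variances are clamped at 1e-6 z-units² to protect silent channels.

The default composition is the top M = 5 principal components of the
z-scored population — the PCA basis is fitted *on the reference bins
only*, with a deterministic sign convention (largest-magnitude loading
entry positive) — plus the decoded velocity X̂ and its one-bin (20 ms) lag,
k = 9 total.  Compositions of X̂ alone (k = 2) and X̂ + X̂_lag (k = 4) are
supported; including the decoder output couples the score to the quantity
the user actually experiences, while the lag pair makes short-timescale
output dynamics (e.g. loss of smooth directional persistence) visible to a
second-moment statistic.

## Reference selection

The reference defaults to bins of the decoder's deployment day with
instantaneous angle error (AE) below 4° — moments of the feature
distribution during demonstrably good control.  AE is the absolute angle
between the cursor-to-target vector and X̂ (0° best, 180° worst).  The
threshold, the session subset, and an optional intended-direction sector
(up/down/left/right, ±45°) are parameters; the threshold can be disabled
entirely for task-agnostic references where AE is unobservable.  Empty
selections raise with per-filter counts rather than silently producing a
degenerate Gaussian.

## Validation machinery

*Windowed median AE* shares the drift trace's exact window grid (trailing
60-s windows, 1-s steps, anchored at block starts, never spanning blocks);
windows with under 50% valid bins are missing.  The median (not the mean)
summarizes AE because its distribution skews toward low values.

*AE-binned KLD* pools valid bins across sessions, groups them into 45
four-degree AE intervals, and scores each interval against the pooled
AE < 4° reference (which is also the PCA-reference data); the Pearson
correlation of KLD against interval midpoints measures how linearly the
feature distribution drifts with performance.

*Pairwise mean KLD* summarizes inter-session distances: windows of 60 s
stepped by 10 s, all M×N window pairs of sessions i and j averaged
(distinct pairs on the diagonal), outlier trials excluded.  The matrix is
asymmetric by construction; a symmetrized (A+Aᵀ)/2 view is offered for
display.

*Cosine tuning.*  y = b₀ + b₁cos θ + b₂sin θ fitted by OLS per feature and
session on z-scored bins from [go cue + 160 ms, +1 s) of non-outlier
trials; every bin is one observation carrying its trial's intended
direction at the go cue (the target direction for center-out; the inferred
intent for random targets).  Significance is the overall F-test at
p < 0.05, with (2, n−3) degrees of freedom; no multiple-testing correction
across features is applied.  ΔMD = MD − MD_ref and |ΔPD| =
min(360° − |PD − PD_ref|, |PD − PD_ref|) are taken against the first day
the feature was significantly tuned.  Bootstrap change detection resamples
*trials* (not bins, respecting within-trial correlation) B = 1000 times
per session, refits, wraps PD differences to (−180°, 180°], and flags a
change when the 95% percentile CI excludes zero.  Tuning maps are the 3×N
(b₀, b₁, b₂) matrices of significant features; cross-session similarity is
the Pearson correlation over features significant on both days (≥ 2
required).  Feature ordering for display uses Ward-linkage hierarchical
clustering of globally standardized ΔMD/ΔPD profiles, NaNs imputed at the
standardized mean.

*Latent VAF.*  Trial-averaged, Gaussian-smoothed (σ = 50 ms) trajectories
per 45° direction sector over the same reach window are concatenated into
Ȳ (C × 8·50).  Rank-2 direction components solve the reduced-rank
regression of the direction-marginalized Ȳ_dir on Ȳ: the unconstrained
least-squares map is computed analytically and projected onto the top-2
principal subspace of its fitted values, yielding encoder F (C×2) and
decoder D (2×C).  Cross-validated regularization and trial-count balancing
are deliberately omitted — only the top two direction components and the
VAF formula R² = (‖Ȳ‖² − ‖Ȳ − FDȲ‖²)/‖Ȳ‖² are needed, and the
unregularized solution is exact and reproducible.  Components are fitted
on day 0 and frozen; later sessions are scored through them.

*Outlier trials* are those with > 5% packet loss or any bin with a channel
value more than 8 SD above that channel's session mean.  The paper-style
amplitude statistics are computed per channel over the whole session
excluding packet-drop-flagged trials — a session-level population is the
least surprising reading where no reference population is specified.
Zero-variance channels are skipped in the amplitude test.  Outlier bins
are *included* in scoring by default (momentary signal deviations are part
of what the score usefully detects) and excluded via a flag.

## The simulator

The simulator exists so every stage above can be tested against known
ground truth.  Its defaults define the study conditions used throughout
the tests and the acceptance script.

* Population: 24 channels, baselines uniform in 40–80 Hz, cosine
  modulation depths 11–23 Hz, preferred directions spread around the
  circle.  Rates follow r_c = max(0, baseline_c + md_c·cos(θ − pd_c)) —
  rectified-linear rather than exponential, matching the linear cosine
  regression the analysis fits so planted parameters are directly
  recoverable.  Counts per 20 ms bin are Poisson (a zero-noise Gaussian
  mode exists for exactness tests).
* Decoder: least-squares map from normalized counts to intended unit
  direction, trained on a 120-trial open-loop calibration run and frozen.
  Input normalization uses the *calibration* channel means/SDs, frozen
  with the decoder; a running output-bias estimate (adaptation rate
  0.3 s⁻¹) is subtracted from the raw velocity, and the output is
  exponentially smoothed, X̂_t = αX̂_{t−1} + (1−α)βv_t with α = 0.92,
  β = 0.35 screen-units/s, speed-capped at 1.  Freezing the input
  normalization is deliberate: an online-adaptive normalizer inside the
  closed loop couples to direction occupancy (slow reaches dominate the
  trailing window, bias the normalizer, and further slow those reaches — a
  positive-feedback lock-in this simulator cannot escape because user
  compensation is out of scope).  The recorded features are still
  normalized adaptively on the *analysis* side, as the score prescribes.
* Tasks: center-out-and-back (8 targets at radius 0.38, acquisition on
  entry) and random-target (uniform targets, 500 ms dwell), 10-s timeout,
  160 ms reaction time after the go cue during which intent holds its
  previous direction.
* Drift: per-session preferred-direction rotation (global or
  per-channel), modulation-depth scaling, baseline offsets (in Hz, applied
  in the rate domain before sampling), channel dropout (baseline-only
  activity), and injected packet-drop or amplitude outlier events.  The
  canonical drifting study rotates each channel by a fixed signed fraction
  (|u_c| ∈ [0.5, 1]) of a magnitude growing linearly to 90° over eight
  sessions while modulation depths shrink to 70%.  The rotation is
  *heterogeneous* on purpose: a uniform global rotation leaves the
  direction-coding population subspace — and therefore the latent VAF —
  unchanged, so it cannot produce the subspace drift the latent analysis
  measures.
* Scale: eight sessions of 120 trials (≈ 8–12 min each), one block per
  session.  Day-0 closed-loop control under these conditions lands at a
  median AE of ≈ 14–18° with > 90% trial success and ≈ 15% of bins under
  the 4° reference threshold, across seeds.

What the simulator does *not* emulate: user learning or compensation
strategies, biophysical spiking detail, spike-sorting instability as
distinct from tuning change, wireless hardware behavior beyond the packet
-drop abstraction, and multi-block session structure effects beyond
z-score restarts.  Passing tests on simulated studies therefore
demonstrate the *internal* consistency of the pipeline — that the score
tracks genuine distribution drift of exactly the kinds injected — not that
real recordings drift in these ways.

## Degenerate inputs and tie-breaks

Even-count medians average the two central order statistics.  Zero-norm
intended or decoded vectors are masked from AE rather than erroring.  The
last AE interval [176°, 180°] is closed to include exact 180°.  PD values
are reduced to [0°, 360°); a wrap that rounds to exactly 360° maps to 0°.
Bootstrap resamples that produce a rank-deficient design are redrawn, with
a 10·B cap.  The 2-Wasserstein helper returns the distance (square root of
the closed-form squared distance).

## Known limitations

The stationary control's trend statistic retains session-level jitter:
windows within a session share that session's closed-loop realization, so
with eight sessions the pooled Spearman ρ against time scatters roughly
±0.15 around zero across seeds even though no drift exists.  The
AE < 4° reference requires the deployment day to contain enough
good-control bins; very poor initial decoders need a higher threshold or
the threshold-free mode.  Correlations between the score and performance
pool windows across sessions and are dominated by between-session drift;
they are not guarantees about within-session sensitivity at second
timescales.
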