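# Methods

## Scope and data model

The package analyzes head-fixed VR contextual-fear sessions: a per-frame
behavioral table (time, position on a 200 cm virtual track, signed
velocity, teleport and shock flags), per-ROI green/red fluorescence traces
at the 15.49 Hz imaging frame rate, and pupil scalars (area, x/y position,
blink area). It starts downstream of movie processing: motion correction,
ROI extraction, and pupil-video segmentation are assumed done by the usual
tools and are out of scope. Because no public recordings exist for this
preparation, a synthetic-session generator with complete ground truth is a
first-class module; all recovery claims in the test suite are claims about
that generator (see "What the synthetic data does and does not emulate").

## Synthetic sessions

**Behavior.** Locomotion is a run/freeze renewal process. Epoch durations
are log-normal (shape σ = 0.6 throughout; the field reports only summary
means/medians of freeze lengths, so the shape is our choice) with
condition-specific mean freeze lengths and long-run freeze fractions:

| condition            | mean freeze (s) | freeze fraction | tuning        |
|----------------------|-----------------|-----------------|---------------|
| pre_shock            | 2.5             | 0.17            | untuned       |
| shock_day            | 2.5             | 0.15            | untuned       |
| post_shock_shocked   | 5.5             | 0.475           | freeze-tuned  |
| post_shock_control   | 4.2             | 0.27            | freeze-tuned  |
| nr_inhibited         | 21.1            | 0.775           | freeze-tuned  |

Mean freeze lengths and fractions for the post-shock and inhibited
conditions take the values reported for those groups (5.5/4.2/21.1 s;
47.8%/26.7%/77.8% freezing); the run-epoch mean is then fixed by the
target fraction, mean_run = mean_freeze · (1 − f)/f. Freeze draws are
clipped at 13 frames so every generated freeze is detectable by the
12-frame criterion; runs are clipped at 4 frames. Running velocity is a
session-mean speed (15 ± 2 cm/s, clipped to 8–25 cm/s) plus slowly varying
noise, floored at 2 cm/s; freezing velocity is exactly 0. Position
integrates velocity; completing 200 cm triggers a 1.5 s teleport pause
back to the origin, and teleports never carry epoch state. Day-0 sessions
insert six 1 s shocks with inter-onset gaps uniform in 20–26 s (first
onset at 120 s; a session too short for the schedule raises). During each
shock and for 1 s after, velocity is multiplied by a sprint factor of 4,
relaxing exponentially (τ = 0.5 s) afterwards — the stereotyped escape
sprint. Post-shock conditions add brief backward-movement bouts
(0.3–1.2 s at −3 cm/s) at a low per-minute rate during running.

**Axon fluorescence.** Each session has one latent axon (optionally
several independent sources for merging tests). Transients are a
per-frame Poisson process: untuned sessions use a homogeneous 0.15 Hz
rate; freeze-tuned sessions use 3 Hz inside freezes modulated by a
ramp–plateau–fall profile (ramp over the first 20% of the epoch from 0.2×
to 1×, plateau, fall over the last 10% to 0.3×) and 0.05 Hz outside.
Amplitudes are log-normal (mean 0.35 Δf/f, σ = 0.35). The green trace is
the amplitude train convolved with a GCaMP6s-like double-exponential
kernel (rise 0.18 s, decay 1.6 s, peak-normalized; the indicator kinetics
are not reported for this preparation, so textbook GCaMP6s values are
used). Both channels share a motion-artifact component (smoothed noise
plus a |velocity|-coupled term, unit SD, gain 0.15) and carry independent
Gaussian noise (SD 0.04); the red channel has no activity term. Traces are
written as baseline · (1 + signal), baselines 100 (green) and 80 (red), so
Δf/f recovers the transient train. The in-freeze rate, amplitude, and
noise defaults were set once to put sessions in the signal-to-noise regime
of the well-predicted axons this analysis targets (encoding r² well above
chance), and are configurable.

**Pupil.** Latent area/x/y are smoothed Gaussian processes; the blink-area
baseline uses bounded uniform noise (±1.5 around 10) so that without
injected blinks no frame can fall below mean − 2 SD — the removal rule
then fires exactly on injected blinks, which zero the blink area and
occlude the pupil for 2–4 frames at a Poisson rate (default 0.05 Hz).

## Behavioral segmentation

Threshold comparisons are strict: freezing needs |v| < 0.001 cm/s,
running v > 0.001, backtracking v < −0.001; a frame exactly at threshold
is neither and lands in `discarded`. Sub-threshold stretches shorter than
12 frames are discarded, as are above-threshold singletons. Epochs are
half-open `[start, end)` on 0-based frames, never span a teleport, and are
numbered 1..n in time order. Percent time freezing divides freeze frames
by freeze + run + backtrack frames; discarded and teleport frames are
excluded from the denominator as un-analyzable (the source analysis
discards sub-criterion stretches "from future analysis"; whether its
denominator also excluded them is not stated — this package's convention
is documented here, not asserted as the original authors'). The
discrimination index is computed per mouse and aggregated by the group
mean. Backtracking summaries split laps into the first `first_n`
traversals versus the rest, with `first_n` exposed because the boundary
between "first" and "early" traversals is a judgment call.

## Trace processing

Processing order is smooth → demean → orthogonalize → Δf/f. The
Savitzky–Golay filter uses window 9 (~0.58 s) and order 3, configurable.
Orthogonalization subtracts the red channel's projection
Cov(g, r)/Cov(r, r) · r from the green channel; the result has exactly
zero sample covariance with the red channel, and the operation is
idempotent. A (near-)constant red channel makes the projection degenerate;
the demeaned green channel is returned with a warning. After
orthogonalization the green channel's mean is restored before Δf/f — the
corrected trace is zero-mean by construction, and a ratio baseline
requires a positive operating point.

Δf/f uses F0 = rolling 8th percentile over a 30 s window (configurable);
the source only says "baseline corrected", and a low rolling percentile is
the standard choice that tracks slow drift without eating transients.
F0 ≤ 0 anywhere raises, as it indicates corrupt input scaling.

ROI merging computes pairwise covariances of corrected Δf/f and compares
each pair against the 99th percentile of its own shuffle null, built from
500 circular time-shifts (offsets ≥ 1 s from zero; circular shifting
preserves each trace's autocorrelation, so the null is "same dynamics,
no alignment"). Covariance, not correlation, is the merge statistic; the
>0.2 correlation figure quoted for multi-segment axons is treated as
descriptive. Linked pairs form connected components; each multi-ROI
component is replaced by the first principal component of its members,
sign-flipped so the mean loading is positive (PC sign is arbitrary) and
rescaled to the members' mean variance and mean offset so merged traces
stay on the Δf/f scale. The calibration property — independent ROIs merge
at ≈ 1% — is verified by Monte-Carlo. Note that two genuinely distinct
freeze-tuned axons covary through the shared behavior and will merge;
statistical independence, not source identity, is what the null tests.

Per-day normalization divides by the 99th percentile of the day's Δf/f
samples. "Near-maximum activity" is read as the percentile of the
frame-wise distribution rather than of peak heights: peak heights are only
defined after detection, whose 0.1 height floor is applied on the
normalized trace, and the sample-based reading avoids that circularity.
Peak detection uses `scipy.signal.find_peaks` with height ≥ 0.1,
prominence ≥ 0.1, and minimum separation round(0.5 s × rate) frames;
conflicts keep the taller peak (earlier on ties). The session-inclusion
("activity") criterion is ≥ 2 peaks reaching 0.1 Δf/f.

## Tuning analyses

Peaks are assigned to the epoch containing their frame. State means
average per-epoch mean peak heights across epochs; a state with no
peak-bearing epoch yields NaN, never zero. Freeze epochs are binned by
duration into 1 s bins from 1–2 s to 6–7 s; epochs over 7 s are excluded.
Transition alignment uses only freeze epochs whose very next frame is a
run epoch; the freeze-side window defaults to the bin's lower edge and the
run side to 2 s; snippets crossing session bounds are dropped with a log
record. Because the indicator decays over ~1.6 s, freeze-evoked
fluorescence spills past the transition; the elevation of freeze-window
over run-window activity is therefore a pooled, across-epoch property, not
a per-epoch one — the tests treat it that way.

Progress profiles divide each epoch (≥ 5 frames) into five even bins by
fractional peak position; a bin with no peak contributes 0 to that epoch's
profile (peaks carry the activity; absence is baseline), with a flag to
skip empty bins instead. Profiles average peak heights, following the
stated definition of the quantity, rather than all trace samples.

Robust fits are Huber M-estimates via iteratively reweighted least squares
with the standardized median absolute deviation as the scale estimate
(statsmodels RLM, the same estimator family the original analysis used),
iterated to coefficient convergence (tol 1e−8, max 50 iterations;
non-convergence raises with the iteration trace). With every residual
inside the Huber threshold the estimate equals ordinary least squares.
The helper `declares_freeze_tuning` operationalizes "freeze-tuned" as a
one-sided Welch t-test (α = 0.05) on per-epoch mean peaks, mirroring the
freeze-vs-run comparisons the field reports; plain mean inequality is too
weak a notion for untuned data, where it holds half the time by symmetry.

## Encoding model

The feature table contains 25 per-frame predictors in six groups
(freezing, velocities, running, interval, location, pupil). Sawtooth
counters count frames from epoch start (elapsed), to epoch end
(remaining), and progress = elapsed/(length − 1) ∈ [0, 1]; interval
counters concatenate freeze and run epochs and reset at switches.
`is_postfreeze` — named in the published feature grouping but never
defined — is 1 within 1 s after a freeze ends (window configurable).
Velocity offsets shift the recorded velocity by ±8 and ±15 frames; the
missing edge frames are filled with the mean of the nearest 15 recorded
frames. Acceleration is the first difference of velocity times the frame
rate; it is absent from the published six-group gain table and is
reported with the velocities group here. Location is the 1 cm position
bin. Pupil channels enter as smoothed raw values (not z-scored; trees are
monotone-invariant). Discarded-state frames stay in the table with all
state indicators 0; teleport frames are excluded at split time because
laps exclude them.

Whole laps are assigned 80/20 to train/test (seed 42, configurable); the
last 10% of training laps form the early-stopping evaluation set. The
XGBoost regressor uses the fixed hyperparameters γ = 1, learning rate
0.01, 1000 estimators, base_score 1, early_stopping_rounds 5,
`tree_method="hist"`, single-threaded for reproducibility. r² = 1 − u/v
with u the residual and v the total sum of squares; v = 0 raises rather
than returning a number. Chance is estimated by permuting lap-blocks of
the target across lap slots (blocks linearly resampled to the slot
length) and refitting at full ensemble size — early stopping terminates
signal-free refits within a few rounds, and a deliberately under-fitted
null would understate chance so badly that clearly unpredictable sessions
appear "significant". Gain importance is grouped by averaging member
gains per group and normalizing the group totals to 1; a feature missing
from the grouping raises.

## What passing tests show — and what they do not

The generator emulates run/freeze alternation with condition-dependent
statistics, shock-evoked sprints, freeze-locked calcium transients with a
within-epoch profile, a shared two-channel motion artifact, and
blink-contaminated pupils. It does not emulate slow behavioral
non-stationarity within a session, across-day axon identity drift,
z-motion or neuropil contamination beyond a single shared artifact
component, context-specific neural differences (tuned activity is
context-independent by construction, as observed in vivo), or reward-era
training behavior. Recovery results therefore demonstrate that the
pipeline's operations are correct and well-calibrated under the stated
generative model, not that in-vivo effect sizes would be reproduced.

## Problem sizes

Default sessions are 322 s (4988 frames) at 15.49 Hz with 3 ROIs.
Monte-Carlo suites use 20 sessions per condition for parameter recovery,
2000 white-noise pairs for merge-null calibration, and 1000 random traces
for segmentation oracle equivalence. The acceptance script uses 8
behavior-level and 10 encoding-level sessions per condition and 1500
merge pairs, sizes chosen to keep the full run around a minute on one CPU
while leaving Monte-Carlo standard errors well inside the asserted bands.
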