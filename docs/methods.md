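# Methods

This note documents the models, defaults and design choices behind
`abpbench`, in the package's own terms. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

An arterial catheter and transducer produce a continuous pressure signal;
the monitor emits systolic (SBP), diastolic (DBP) and mean (MAP) pressure
and heart rate (HR) once every 5 s (1/5 Hz). The AIMS stores one value per
channel per minute: the median of the twelve samples in the half-open
window `[t_end − 60, t_end)`, with boundaries at multiples of 60 s from
session start. Whether a real AIMS aligns boundaries to wall-clock minutes
or device start is vendor-specific; we align to session start and say so.
Half-open windows prevent a sample from contributing to two minutes.
Minutes with fewer than 12 contributing samples still store a median
(configurable minimum, default 1); empty minutes store nothing.

Medians are robust to short disturbances, which is exactly why short
artifacts rarely corrupt stored values — and why annotation strategies that
see only stored values miss them.

## Synthetic sessions

The simulator emulates the *statistical situation* of a monitored
anesthesia session, not waveform physiology (no 125 Hz waveforms, no ODE
hemodynamics). Design:

- **Baselines.** SBP, DBP and HR follow independent bounded random walks
  (reflection at ±30/±20/±25 around the configured baselines; step SD
  `trend_sd`, default 0.5 mmHg per 5 s step), plus additive observation
  noise (`noise_sd`, default 1.5 mmHg). After noise, DBP is floored at
  20 mmHg and SBP at DBP + 5, and MAP is computed as DBP + (SBP − DBP)/3,
  so the clean-sample ordering SBP ≥ MAP ≥ DBP > 0 holds exactly.
- **Episodes.** Onsets per cause follow a Poisson process
  (`episode_rate_per_hour_by_cause`), durations uniform in
  `duration_range_by_cause`. Episodes may overlap; the per-sample truth
  flag is the union. A landmark flush is always injected in the first
  120 s with duration ≥ 10 s so its plateau covers at least two grid
  samples.
- **Cause signatures** (configurable; the taxonomy is the six observer
  categories, the numeric shapes are this package's choices):
  flush → non-pulsatile plateau ≈ 280 mmHg (5–15 s); blood sampling →
  damped non-pulsatile 30–60 mmHg (20–60 s); sensor movement →
  heavy-tailed t₃ spikes, SD 40 mmHg, on all channels (5–90 s);
  simultaneous NIBP → pulse pressure compressed by 70% around MAP
  (30–60 s); sensor height → constant ±10–30 mmHg offset on all three
  pressures (60–600 s); other → mild multiplicative distortion (10–60 s).
  Flush signatures are applied last because the pressurized flush bag
  dominates the transducer; an overlapping disturbance cannot erase the
  landmark. HR is left undistorted by pressure-only causes (it derives
  from a separate signal in practice), keeping HR features informative.
- **Default rates** (0.2/0.4/0.6/0.5/0.1/0.3 per hour for
  flush/sampling/movement/NIBP/height/other) were chosen once so that a
  1 h session carries an any-overlap artifact burden of several percent
  of minutes and a >30 s burden near 2% — the regime where chance-corrected
  agreement is the meaningful metric. They are conditions, not estimates
  of any particular cohort.
- **Clocks.** The observer log is the true episode list shifted by
  `clock_offset_s` (observer minus monitor, default 30 s); the logged
  flush time is the true flush onset plus the offset. Times are integer
  seconds on a 5 s sample grid, so overlap arithmetic is exact.
- **Retrospective annotator.** Each artifact minute (under the >30 s rule)
  is detected with a cause-dependent probability
  (`retro_detect_prob_by_cause`, defaults 1.0/0.22/0.13/0.17/0.54/0.38 for
  flush/sampling/movement/NIBP/height/other — sustained systematic errors
  are easy to spot in stored trends, brief movement is nearly invisible
  after the median); clean minutes flip with `retro_false_pos_rate`
  (default 0.015). This is a Bernoulli emulator of a human rater, not a
  model of one: it has no within-rater correlation, no drift, and no
  difficulty gradient within a cause.

Determinism: every stochastic choice flows through one seeded generator;
identical config + seed reproduces a session bitwise.

## Labels

Episodes are half-open `[start, end)`; "any overlap" means strictly
positive measure (a zero-length touch does not label). Definition 2 is
strict: exactly 30.0 s does not qualify. Per-minute totals use the union
across causes, so overlapping episodes are not double counted; the
per-minute cause is the one covering the most seconds, ties broken by the
earliest overlapping episode start. Definition 4 flags a 1/5 Hz sample iff
its timestamp lies in some episode.

## Features

Nine feature types per data point: SBP, DBP, MAP, HR, pulse pressure, and
the ratios SBP/HR, DBP/HR, SBP/MAP, MAP/DBP (zero denominators become
NaN, flagged rather than raised). Per type: the current value plus the
differences (current − neighbor) to the five preceding and five following
points — 11 columns, 99 total. For the four core signals, a summary block
over the same 11-point window: median, current − median, and
(current − median)/median — 12 columns, 111 total. High-rate mode takes 15
neighbors either side at 20 s spacing (every 4th sample): 31 columns per
type plus the summary block over the 31-point strided window, 291 total.

Two counting choices deserve a note. First, computing *both* the
median-based and mean-based summary triples would give 123/303 columns;
the default ("paper") mode keeps the median-based triple only, which is
the unique reading consistent with the totals 111 = 9·11 + 4·3 and
291 = 9·31 + 4·3; `mode="extended"` exposes the full set. Second,
differences are current − neighbor throughout; the sign convention is
irrelevant to the learners but fixed for reproducibility.

Rows whose window is incomplete (series edges, or gaps in the minute/5 s
grid) are masked, not imputed: the first/last 5 minute rows and the
first/last 60 high-rate samples (±300 s at 20 s spacing) of a gap-free
series are masked. Downstream model fitting drops masked and non-finite
rows.

## Agreement statistics

With live annotation as reference: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), each reported missing on a zero denominator.
Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with the standard marginal-product
chance term; a degenerate single-class table (p_e = 1) is defined as κ = 0.
Internal values are never rounded; display rounding is half-up, 2 decimals
for proportions and 1 for percentages. Missing labels are excluded
pairwise before tabulation.

## Learners

Row-wise 0.8/0.2 train/test assignment (independent Bernoulli per row,
seeded). Row-wise splitting intentionally reproduces the window-overlap
leakage inherent in treating each data point as independent — neighboring
rows share window content; a grouped (per-session) split would be the
leakage-free alternative and can be had by splitting `assemble_design`
inputs by session before stacking.

Hyperparameters are tuned by stratified fourfold CV on the training set
only, maximizing the mean out-of-fold kappa; ties resolve to the
most-regularized point (largest lambda/decay, smallest C) by grid
ordering. Stratification is necessary at a ~2% positive rate. Default
search ranges: lasso lambda log-spaced in [1e-7, 1] (20 points; the
L1-only limit of elastic net, i.e. mixing parameter 1); network hidden
sizes 2–20 with weight decay log-spaced in [1e-7, 10] (9 points); SVM cost
C log-spaced in [5e-4, 1e3] (8 points) and Gaussian kernel width sigma in
[5e-4, 0.2] (7 points). `HyperGrid.small()` provides coarse sub-grids of
the same ranges for quick experiments and the test suite. The lasso's
lambda refers to a 1/n-scaled objective and maps to scikit-learn as
C = 1/(n_train · lambda).

All three families standardize features with training-row statistics
(re-estimated inside each CV fold via a pipeline), since the network and
SVM are scale-sensitive. Classification threshold is 0.5 on predicted
probability (decision-function sign for the SVM). Test metrics are
computed once, on held-out rows only; the results object retains fold
assignments and out-of-fold predictions so the reported CV kappa can be
recomputed exactly, and exposes the fitted standardizer for leakage
audits.

## Problem sizes

The test suite and acceptance script run on deliberately modest problem
sizes chosen as adequate for the statistical checks they carry: single 1 h
sessions for structural checks, 50 × 2 h sessions for the Monte-Carlo rate
check, 100 × 10 min sessions for clock-offset recovery, 10 000 emulated
minutes for annotator calibration, and a 20-session (~1000 minute-rows)
fixture with coarse grids for the learner benchmark.

## Known limitations

- The simulator's signatures are stylized stand-ins; no published
  magnitudes or durations per cause exist to estimate them from, so
  passing benchmarks demonstrate pipeline correctness and qualitative
  behavior, not expected performance on real monitor data.
- In the benchmark fixture, sensor-height offsets take either sign with
  equal probability; a linear model cannot separate a sign-symmetric
  level shift, so the lasso's kappa on retrospective-style labels is
  structurally depressed there while the kernel SVM and the network
  handle it — compare families accordingly.
- The retrospective annotator is memoryless; real raters are not.
- Minute boundaries are anchored at session start; real AIMS exports may
  anchor elsewhere, which would shift every overlap computation by a
  constant.
- No confidence intervals are attached to agreement statistics or kappas.
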