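# Methods

This note documents the models, processing rules and design choices behind
`parabospine`: what each stage computes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## The measurement problem

During a parabolic flight the load factor along the body axis (Gz) cycles
through level flight (~1 g), a pull-up (~1.8 g), ~22 s of free fall (~0 g)
and a pull-out (~1.8 g), roughly 31 times per flight with each participant
measured over 10–11 parabolas. Two instruments observe the spine
throughout:

* a backplate carrying 15 laser distance sensors (topmost at C7, pitch
  3.0 cm on the short plate / 3.5 cm on the long plate, accuracy
  ±0.05 mm, effective rate ≈1.26 Hz) measuring plate-to-skin distance —
  the profile of the back relative to a rigid reference;
* five wireless surface-EMG transmitters (2000 Hz, hardware band
  10–500 Hz) on the erector spinae at four heights from L4 upward (right
  side) and the multifidus at L5 (left side), each with a 148 Hz
  accelerometer.

Neither device shares a clock with the aircraft's gravity recording, and
the quantities of interest are defined per gravity condition, so the
pipeline is: synchronize → segment → window → summarize → test.

## Synchronization and segmentation

**Clock offsets** are estimated by normalized cross-correlation between
each device's accelerometer channel and the operator gravity trace, both
resampled to a common 10 Hz grid. The lag at the correlation peak is the
device's clock offset; subtracting it puts the stream on the reference
clock. Resolution is one resample interval (0.1 s), far finer than the
shortest analysis structure (10 s plateaus). A peak below 0.5 normalized
correlation raises an error rather than returning a garbage offset.

**Segmentation** thresholds the gravity trace into bands — micro
|Gz| ≤ 0.1 g, earth 0.9–1.1 g, hyper ≥ 1.5 g (all configurable). The bands
comfortably separate the plateaus, whose observed means are 1.00 / 1.79 /
−0.00 g. Before thresholding the trace is smoothed with a 0.5 s moving
average, and same-band runs separated by gaps under 1 s are merged, so a
single noisy sample cannot split a plateau; runs shorter than 10 s are
discarded, which removes the ~3 s ramps. Runs are grouped into parabolas
by the hyper–micro–hyper motif, with the immediately preceding level-flight
run attached as that parabola's earth segment. Both hyper phases are kept
as separate segments and pooled into the single hyper condition later (see
*Condition weighting* below).

One geometric caveat: a threshold rule on a finite ramp necessarily crosses
the band boundary slightly before the plateau begins, by
(band half-width)/(ramp slope). For the micro band this is under one
sample at 10 Hz; for the earth and hyper bands it is 0.4–1.1 s. This bias
is irrelevant to every downstream quantity because analysis windows are cut
centrally from each segment and never reach its edges, but it means
segment boundaries should not be read as plateau boundaries for the wider
bands.

**Windows.** Distance analysis uses a fixed 17 s window per segment (the
0.25 quantile of segment durations in the reference campaign); EMG uses
14.86 s (the shortest recorded segment). Windows are centered in the
segment — the placement is not dictated by the data source, and centering
discards boundary transients symmetrically. `window_quantile` exposes the
linear-interpolation quantile used to derive such lengths from a cohort's
own durations.

## Curvature statistics

Each windowed profile is the per-sensor mean distance over in-window
samples. Cleaning rules, in order:

1. the topmost sensor (C7) is always excluded (chronically unreliable);
2. a sensor masked by a bra elastic is replaced by the mean of its two
   vertical neighbours (never cascaded);
3. sensors missing for a whole segment are clamped to their recording
   limits — 16 mm floor at sensors 8–10, 120 mm ceiling at sensor 2 —
   because an out-of-range posture saturates at a known bound; dropouts at
   other sensors stay missing;
4. sensors positioned below the inter-SIPS line, i.e. whose distance from
   C7 ((index−1)·pitch) exceeds the participant's measured C7–SIPS trunk
   length, are excluded.

**Enclosed area** is the trapezoidal integral of distance over sensor
position (mm²) across consecutive included sensors — the standard
quadrature for an irregularly sampled profile. It is a *proxy* for spinal
curvature: it decreases when the spine flattens toward the plate, but no
anatomical landmark mapping is attempted. Adding a constant c to every
sensor adds c×span to the area (shift equivariance), which is why all
inference runs on normalized values.

**Inter-sensor angles.** Sensor i is embedded at plane point
(d_i, (i−1)·pitch) and the angle at each interior sensor is computed from
the law of cosines on the vectors to its neighbours. The raw planar angle
is always ≤180°, so a sign convention is needed to encode curvature
direction: when the middle distance exceeds the chord (mean of the
neighbours) the profile bulges away from the plate and the raw angle is
reported (lordotic, <180°); below the chord the reported angle is 360°−raw
(kyphotic, >180°); collinear sensors give exactly 180°. The convention is
verified against an independent cross-product-based oracle on random
profiles to 1e−9.

**Normalization.** Mean normalization expresses each record as a percent
of the participant's grand mean (the participant mean of the result is
exactly 100 by construction); earth normalization divides by the
participant's earth-condition mean and is used for the association
analysis. Normalization removes trunk-size differences and any shared
multiplicative factor.

**Condition weighting.** Each parabola contributes one earth, two hyper
and one micro window. Before normalization the two hyper windows are
averaged into a single hyper record, so every condition carries equal
weight per parabola. This matches the balanced weighting evident in the
reference campaign's normalized condition means (each assessment's three
condition means average to exactly 100) and keeps the grand-mean reference
from being dominated by the doubled hyper windows.

**Parabola-order check.** For each participant the per-parabola
mean-normalized area (averaged across conditions) is reduced to three
cells — first parabola, mean of intermediates, last — and a
Greenhouse–Geisser adjusted repeated-measures ANOVA tests for an order
effect. If present, the first parabola is excluded.

## EMG chain

Raw channels are filtered with a second-order Butterworth band-pass at
10–500 Hz and rectified. The filter is applied forward–backward
(zero-phase): segment RMS is phase-insensitive, and a causal filter's group
delay would misalign the analysis windows; the effective order doubles,
which is documented rather than compensated. The 500 Hz cutoff sits below
the 1000 Hz Nyquist of the 2000 Hz channels and is validated.

Per segment, the summary is the RMS over the 14.86 s window. Outliers
beyond 3×IQR from the first/third quartile of a participant-site's RMS
values are flagged but retained — detection motivates the robust order
test; the robust test accommodates them (a strict mode can delete instead).

**Order effect.** Segment RMS per parabola is reduced to
{first, intermediate-mean, last} per participant and site and tested with a
robust repeated-measures ANOVA on 20%-trimmed condition means: the error
term is built from column-Winsorized residuals, degrees of freedom are
(k−1)ε and (h−1)(k−1)ε with h = n − 2⌊0.2n⌋ and a GG-type ε estimated on
the Winsorized data. At zero trimming this reduces exactly to the
classical GG ANOVA (tested), and its null rejection rate is verified by
simulation. If any site shows a significant order effect, the first
parabola is excluded for **all** EMG sites — a novelty/startle effect is a
property of the flight, not one electrode.

ECG crosstalk is deliberately **not** removed: the recordings contain it,
it could not be removed there either, and the generator quantifies its
bias instead of the pipeline pretending to subtract it.

EMG normalization mirrors the area: grand-mean (100% = the participant's
average activity at that site across conditions) or earth-mean for the
association analysis. Retained-segment closure at exactly 100% is a tested
invariant, as is invariance to any positive rescaling of the raw channel
(so amplifier gain cannot matter).

## Statistical battery

Every Bonferroni family size is an explicit argument, never inferred:
pairwise post hocs use m = 3 (three condition pairs); the erector spinae
Friedman and Spearman batteries use m = 4 (four ES sites); the multifidus
is tested alone, uncorrected. Incomplete repeated measures are handled by
listwise deletion, which is why n varies by assessment.

* **Normality gate.** Shapiro–Wilk per cell plus a 3×IQR extreme-outlier
  screen; the parametric path (RM-ANOVA + paired t) requires every cell
  normal and outlier-free, otherwise the nonparametric path (Friedman +
  Wilcoxon signed-rank) is indicated. Cells with n < 3 or zero variance
  are untestable and route nonparametric.
* **GG RM-ANOVA.** One-way repeated-measures F with both degrees of
  freedom multiplied by the Greenhouse–Geisser sample ε, computed from the
  eigenvalues of the double-centered condition covariance; ε is clipped to
  [1/(k−1), 1] and equals 1 exactly for k = 2. Verified against an
  independent reference implementation to 1e−6.
* **Paired t + post-hoc power.** Two-sided paired t per condition pair;
  power from the noncentral t distribution with ncp = d√n at the
  Bonferroni-adjusted α, matching numerical quadrature to 1e−4.
* **Friedman.** Mid-ranks with the standard tie correction. The p-value
  is exact — computed by dynamic programming over the permutation
  distribution of column rank sums — whenever that is cheap (always for
  n ≤ 8; for k = 3 up to n = 25), else the χ²(k−1) approximation. The
  exact path matters at cohort size: the χ² approximation is noticeably
  conservative at n ≈ 17.
* **Wilcoxon signed-rank.** Zero differences dropped (classic
  convention); W is the positive-rank sum; exact p for n ≤ 25 without
  ties, normal approximation with continuity correction otherwise. Exact
  p-values agree with full 2ⁿ sign enumeration.
* **Spearman.** Mid-rank correlation over complete cases; n < 4 is
  refused.

Because the exact rank tests are discrete, their attainable size at the
p < 0.05 rule is slightly below 0.05 (0.0448 for Wilcoxon and 0.0461 for
Friedman at n = 17, both computable in closed form from the permutation
null); the calibration tests check empirical rejection rates against
binomial bounds centered at those attainable sizes, and at the nominal
0.05 for the continuous tests.

## Synthetic-data generator

The generator exists so that every stage is verifiable without the study's
(undeposited) recordings. It emulates, per participant:

* **Flight profile**: the plateau/ramp structure above with linear ramps
  (3 s default — the true transition shape is unspecified and the windows
  discard ramps anyway), Gaussian trace noise (default sd 0.01 g), and
  ground-truth per-sample labels. Trace rate defaults to 10 Hz
  (configurable; the operator feed's true rate is not public).
* **Distance stream**: baseline profile (a smooth thoracic-apex/lumbar-
  bulge template plus participant variation) with condition deltas —
  micro-g flattening concentrated at sensors 7–12 where the observed area
  reduction localizes, a small hyper delta, and an optional uniform
  per-condition plate shift (posture/backpack shift) — cross-faded over
  ramps, plus slow sinusoidal drift (0.2 mm, ~90 s), Gaussian measurement
  noise (0.05 mm, the sensor accuracy), clipping to recording limits and a
  device clock offset.
* **EMG**: band-limited (10–500 Hz) Gaussian carrier normalized to unit
  RMS and multiplied by an envelope equal to the site's baseline RMS times
  a per-condition multiplier; a fixed-rate (72 bpm) biphasic pulse train
  emulates ECG crosstalk; a 148 Hz accelerometer sidecar mirrors the
  gravity trace with the device's clock offset. No motor-unit physiology
  is modeled — the envelope-RMS structure is all the pipeline measures.

**Effect structure** (`EffectConfig.table_patterned()`) encodes the study
conditions: per-participant condition multipliers drawn around the observed
mean-normalized condition means — micro area ratio 0.939 (≈6% reduction),
hyper 1.005, with between-participant SDs chosen so the *realized*
normalized condition SDs land on the observed spreads (≈1.9/2.2/3.6% for
area); EMG site multipliers patterned on the observed per-site condition
means; a shared within-participant activation factor (correlation 0.5
between a site's condition multipliers) that preserves the marginal SDs
while producing the strong paired consistency the observed signed-rank
statistics imply; a latent correlation of 0.8 between a participant's
micro-g flattening and their micro-g EMG multiplier at the lower sites
(ES lower, MF), which after earth-normalization realizes rank correlations
near the observed 0.67–0.69; and a 15% first-parabola EMG elevation
(novelty) that the order-effect screen is expected to catch.

`EffectConfig.null()` removes every condition effect for calibration runs.
Its between-condition variation comes from the per-condition plate shift
with a heteroscedastic, correlated covariance (SDs 1.2/1.4/2.2 mm
patterned on the observed condition spreads; loaded conditions most alike;
true GG ε ≈ 0.6): a genuinely non-spherical repeated-measures covariance,
which is both the realistic case and the regime the GG correction is for —
under an exactly compound-symmetric null the GG test would simply exhibit
its well-known conservatism.

**Segment-level shortcut.** `simulate_segment_summaries` draws the same
participant parameters as the full generator and emits what the windowing
stages would produce — one enclosed area per window and one RMS per EMG
segment, with within-participant noise (1% of area, 8% of RMS per
segment). Replication-heavy studies (power, type-I calibration, recovery
across 100+ cohorts) run on this shortcut in milliseconds; its agreement
with the full signal chain is tested separately on identical participants.
Full-signal EMG at 2000 Hz across five sites is generated and processed in
the end-to-end tests, but not inside replication loops.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: backpack shifts correlated with gravity within a
condition, clothing intrusions, electrode detachment and motion-sickness
dropouts (exclusion reasons exist in the bookkeeping but are not
stochastically generated), non-Gaussian EMG amplitude distributions,
heart-rate variability in the ECG artifact, and any true biomechanics —
effects are injected phenomenologically, so parameter recovery demonstrates
that the *pipeline* measures what was injected, not that the physiology is
as modeled.

## Problem sizes and numerical choices

Cohort studies use n = 17 participants with 10 parabolas each (the
per-participant exposure in the campaign); single-flight checks use the
full 31 parabolas. Parameter-recovery tests run 100 seeded replicates;
type-I calibration runs 2000 null replicates. The curvature recovery runs
the real distance pipeline per replicate; only the EMG branch uses the
segment-level shortcut.

Degenerate inputs resolve explicitly rather than by exception where a
convention exists: zero-variance differences give t = 0, p = 1; fully tied
Friedman blocks give χ² = 0; all-zero Wilcoxon differences give W = 0,
p = 1; a constant list has IQR 0 and flags no outliers; collinear sensors
give exactly 180°. Quantiles are linear-interpolation quantiles.
Bonferroni correction is min(1, m·p) always.

## Known limitations

* The enclosed area is a unit-bearing proxy (mm²) whose absolute value
  depends on plate geometry; only normalized values are comparable across
  participants, and no vertebral-level mapping is attempted.
* Per-sensor distance deviations and angles are reported descriptively
  (profile summary table); no per-sensor inference is performed.
* The robust trimmed ANOVA's small-sample size is approximate (its df
  adjustment is an ε-type approximation on Winsorized data); its
  calibration is demonstrated by simulation at the cohort sizes used, not
  proven.
* Cross-correlation synchronization assumes the gravity signature
  dominates the device accelerometers; vibration-dominated sidecars would
  need band-limiting first.
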