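# Methods

This note records the models and conventions the package implements, the
choices made where the underlying procedures are underspecified in the
literature, and what the synthetic cohorts do and do not establish.

## Epoch model and quality control

Activity is a uniformly sampled non-negative count series (30-s epochs by
default; any epoch length dividing 86 400 s is accepted). Gaps are never
imputed: a missing or off-wrist epoch invalidates the containing 24-h day,
because the non-parametric rhythm formulas assume complete series.

Inclusion requires at least **5 consecutive complete 24-h days**. The day
boundary defaults to local midnight and is configurable; all
participant-level phase statistics use circular means, so the boundary
choice does not leak into results (tested). Night-only wear is detected
per day: a day fails when more than 20 % of its 08:00–20:00 epochs lie in
zero-count runs of ≥ 30 min or are off-wrist flagged; more than one
failing day excludes the participant. Both thresholds are configuration.
Daylight-saving transitions inside the recording window raise a QC flag
but never exclude on their own. Timestamps are treated as naive local
clock time throughout.

## Sleep scoring

The scorer is the published weighted-moving-average rule of the Actiwatch
family adapted to 30-s epochs: weights (1/25, 1/25, 1/5, 1/5, 2, 1/5,
1/5, 1/25, 1/25) centred on the epoch, zero-padding at the boundaries,
wake iff the weighted sum exceeds the threshold (default 40, the device's
"medium" setting; kernel and threshold configurable). Proprietary
scorers may differ in unpublished details; all parameters are exposed so
alternatives can be emulated.

Nightly rest intervals come from diary bed/wake times (optionally snapped
to the nearest scored sleep/wake transition within a configurable
window); without a diary the template-matched offset of day *k* is paired
with the onset of day *k + 1*. Within an interval, sleep onset is the
first run of ≥ 10 consecutive sleep-scored minutes (configurable). TST is
sleep-scored time from onset to interval end, WASO the wake-scored time
over the same span, and everything before onset is latency; hence
latency + TST + WASO equals the interval duration exactly, every night,
and SE = 100·TST/duration. (Counting pre-onset sleep fragments into TST
would break this identity; the adopted convention matches the device
family's sleep-period bookkeeping.) Diary naps are scored identically but
reported separately and never enter nightly TST/SE/WASO.

One consequence of any windowed scorer: the kernel reaches ±2 min across
the morning rise, so even a noiseless sleeper accrues up to ~2 min of
scored WASO at the end of the interval. Tests bound this rather than
asserting zero.

## Phase markers

Onset/offset use a step template of 5 h "low" then 5 h "high" (reversed
for offsets) slid over every bin boundary with circular wrap across
days. A bin is "active" iff its value exceeds the participant's median
bin value — a scale-free criterion; ties at the median count as active
when the median coincides with the maximum (otherwise a majority-active
day binarizes to all-low). The earliest maximal-score boundary wins, a
deterministic tie-break. Template matching runs on 15-min bins by
default (configurable, ≤ 1 h).

The cosinor fit is per-day OLS on the linear sine/cosine
parameterization; acrophase is the clock time of the fitted peak.
Zero-variance days yield amplitude 0 and an undefined (NaN) acrophase.
Participant-level onsets, offsets and acrophases are circular means
(mean resultant direction), so offsets near midnight do not wrap into
artefacts; MESOR and amplitude are arithmetic means.

## Non-parametric circadian statistics

IS and IV follow the classical hourly-bin formulation; a `bin_hours`
flag exposes finer-resolution variants. IV is computed over the
concatenated retained days without resetting at day boundaries (the
successive-difference sum is defined on the full series); values
slightly above 2 occur for anticorrelated series and are legitimate.
L5/M10 default to the average 24-h profile (per-day search with
averaging available via `l5m10_mode="per_day"`); windows wrap across
midnight and ties break to the earliest start. Degenerate (zero-variance
or zero-activity) inputs raise a typed error instead of returning
numbers.

## Spectral measure

The series is mean-subtracted, optionally Hann-tapered (default
rectangular), Fourier-transformed, and powers normalized by total non-DC
power. The circadian statistic is the maximum relative power at periods
in [18, 30] h, with a bandwidth correction (multiplied by the
zero-padding factor, capped at 1) so padding refines the period grid
without diluting the statistic; `band_mode="integral"` sums the band
instead. Proprietary circadian software does not document its
normalization; this definition is the package's own, chosen for
reproducibility and a realistic dynamic range (~0.1–0.4 on plausible
data).

## Inferential protocol

Per outcome, the two-factor cell-means residuals pass a Shapiro–Wilk
gate at α = 0.05: normal residuals go to the permutation ANOVA,
non-normal to per-factor Kruskal–Wallis (tie-corrected, no interaction
term). The permutation ANOVA uses Type-II sums of squares (each main
effect tested against the model containing the other main effect,
ignoring the interaction; the interaction against both mains) with the
full-model residual mean square, and the Freedman–Lane scheme: the
tested term's reduced-model residuals are permuted, the outcome
reconstructed, and the term's F recomputed; p = (1 + #{F* ≥ F})/(1 +
n_perm), default 9 999 permutations, seeded and bit-reproducible.
Globally constant outcomes return F = 0, p = 1 for every term. Empty
interaction cells are dropped from the design so unbalanced cohorts stay
full rank.

Holm correction is step-down with monotonicity enforcement. The default
family is **per factor across outcomes** (all group tests of the measure
battery form one family, likewise all age tests); per-model families are
available by configuration since family assignment in published tables is
usually ambiguous. Note Holm is order-invariant and deterministic but
not idempotent — re-correcting corrected p-values is meaningless and
not supported behaviourally.

The hierarchical cognitive models regress an outcome on IS plus SE, age,
gender (two-level indicator) and number of recorded weekend days, with a
task-accuracy covariate for the reaction-time outcome. Stated
transformations (log for verbal recall and object-context binding,
square root for visual recall) are applied first; outcome values more
than 3 SD from the mean (transformed scale) are excluded with their ids
logged; rows with missing covariates drop per model (complete case). The
IS×age interaction (age continuous) enters in a second step and is
retained iff its p ≤ 0.10 **or** a nested-model F-test at α = 0.05 shows
it contributes to R² — the latter operationalizes "contributes
significantly to the multiple R²", for which no published criterion
exists. Rank-deficient designs raise an error naming the most collinear
pair.

## Synthetic cohorts

The generator emulates the data-generating situation of a wrist-worn
cohort study: seven fully observed nights (recording noon to noon, so
six complete midnight-aligned days survive trimming), per-night timeline
quiet-wind-down → diary bedtime → short latency → sleep → morning rise,
with a shared per-night Gaussian phase shift (controls IS) plus small
independent bed/wake jitters. Sleep epochs are mostly zero with a small
gamma baseline; Poisson-placed arousal bouts (gamma durations, elevated
gamma counts) control WASO and L5. Daytime counts are gamma noise whose
mean is shaped by a gentle 24-h envelope peaking at the target acrophase
and by **positive activity bursts**: half-wave-rectified sinusoids, one
clock-locked 8-h "routine" component with a fixed per-participant phase
(repeats daily, so it loads the stable profile) and one random-phase
ultradian component per day (loads day-to-day variance). Bursts raise
ultradian-band spectral power and hour-scale variability without
creating sub-median dips, which would bias the step-template phase
markers inward. A per-day lognormal amplitude factor adds day-scale
variance. Cognitive outcomes for the DS groups are linear in each
participant's *measured* IS and age with planted coefficients
(positive for reaction time, negative for verbal and scene recall by
default) plus Gaussian noise, so the inferential stage can be checked
against known truth. Everything is bit-reproducible given (parameters,
seed).

The six presets reproduce the target group means (sample sizes 20/20/28/
13/10/10; sleep timing, WASO, IS/IV, L5/M10) within three standard
errors (printed SD/√n) over a 50-seed ensemble — a generator-fidelity
check, not a claim about real data. One documented residual: the
spectral circadian fraction runs ~0.05–0.1 above the corresponding
printed values for the lower-FFT groups; within this generator family
the admissible hour-scale variance is pinned by the IV targets, and the
extra broadband power needed to depress FFT further cannot be added
without violating them. The FFT fidelity check therefore uses a ±0.1
tolerance.

What passing tests show: the pipeline recovers planted sleep timing,
fragmentation, stability and regression structure at the study's sample
sizes, and its tests are calibrated (type-I error 3–7 % at α = 5 %).
What they do not show: fidelity to real wrist-accelerometer noise
(non-stationarity, posture artefacts, device saturation), diary
misreporting, or weekday/weekend schedule structure — diary times are
exact by default so scoring error is attributable to the scorer alone.

## Numerical conventions and problem sizes

All permutation procedures and simulations take explicit seeds; tests
and the acceptance script derive child seeds from one root. Default test
problem sizes — 50-seed calibration ensembles of single participants per
preset, 1 000 null replicates at 399 permutations for the type-I check,
100 seeds at n = 39 for coefficient recovery — were chosen to hold
Monte-Carlo standard errors comfortably inside the asserted tolerances.
Degenerate inputs (constant series, zero-activity windows, empty factor
levels) raise typed errors or flags rather than NaNs. Clock times are
reported in decimal hours on [0, 24); a circular mean that rounds to
exactly 24.0 is mapped to 0.0.
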