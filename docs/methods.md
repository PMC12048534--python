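# Methods

This note documents the models and procedures `actisym` implements, the
defaults and why, what the synthetic generator does and does not
emulate, and the numerical conventions adopted where the underlying
methods left choices open.

## Signal reduction

Raw input is a uniformly sampled stream of tri-axial acceleration (g),
skin temperature (°C) and ambient light (lux); the reference device
class records at 10 Hz with ±8 g range, though any rate giving an
integer number of samples per 5 s is accepted.  Calibration applies
supplied per-axis offsets and gains (`(value − offset) × gain`);
sphere-fit autocalibration is out of scope.  Two epoch grids are
derived, both aligned to the recording start with half-open `[start,
end)` intervals:

* **1-minute grid** — mean ENMO (`max(|a| − 1, 0)` per sample), ROCAM,
  minute-mean light, and `t_smooth`, the centered 5-minute rolling mean
  of minute-mean temperature.
* **5-second grid** — the z-axis elevation angle
  `atan2(az, sqrt(ax² + ay²))` computed on per-epoch axis medians.

ROCAM's published formula is in work we do not reproduce here; the
convention adopted is the mean absolute first difference of the
acceleration vector magnitude within the epoch (units g per sample
interval).  It is zero for a frozen signal, scales linearly with
within-epoch fluctuation amplitude, and is isolated behind one function
so an alternative convention can be swapped in.  The 0.025 non-wear
threshold is interpreted in these units and is configurable.

Timestamps are local civil time without DST adjustment.  Days are
0-indexed from the first midnight; PA days are midnight-anchored and
sleep days noon-anchored.

## Non-wear detection

Two passes over the minute grid (`NonwearConfig` holds every constant):

1. **Long pass (≥ 90 min).**  Candidate minutes satisfy `t_smooth < T0`
   or `Δt_smooth < −0.5 °C/min`, with `T0 = max(26 °C, P5)` where P5 is
   the 5th percentile of all smoothed readings (linear-interpolation
   percentile).  Maximal candidate runs of ≥ 90 min whose **mean** ROCAM
   is below 0.025 are non-wear (the mean-vs-median statistic is
   configurable); detected runs separated by < 15 min are fused with the
   gap.
2. **Short pass ([15, 90) min).**  `T1 = min(mean_worn − sd_worn,
   24 °C)` over pass-1 worn minutes, overridden by P5 when P5 > T1, and
   forced to 24 °C when fewer than 3 full days (4320 minutes) were worn.
   Candidate runs outside pass-1 intervals of length in `[15, 90)` with
   mean ROCAM < 0.025 are kept only when the mean of `t_smooth` over the
   run's first 5 minutes exceeds that over its last 5 minutes by ≥ 2 °C.
   The 2 °C rule operates on smoothed temperature (the series every
   other clause consumes); a run of exactly 90 min belongs to pass 1.

**Limitation (inherent to the percentile fallback).**  When a recording
contains very little true non-wear, the 5th percentile of all readings
falls inside the worn-temperature distribution, candidate runs absorb
adjacent worn minutes, and embedded events are then rejected by the
run-mean ROCAM gate.  The detector is reliable when non-wear exceeds
roughly 5 % of the record — the realistic regime for multi-week
free-living data — and the standard fixture suite is built at that
density.

## Sleep

A 5-s epoch is *sustained inactivity* when it lies in a maximal run of
≥ 5 min over which every successive z-angle change is below 5°; non-worn
epochs break runs.  The SPT window per noon-to-noon night uses a
simplified heuristic: inactivity runs ≥ 30 min are candidate blocks,
blocks separated by < 60 min are fused, the longest fused block wins,
and ties go to the block containing 03:00.  (The percentile-adaptive
threshold of the original heuristic is deliberately not reproduced;
the block minimum and fusion gap sit in `SleepConfig`.)  One SPT per
night; multi-period sleep detection is out of scope.  Sleep duration is
the inactive time within the SPT, WASO the remainder, so
`sleep + WASO = SPT length` exactly.

The detector conflates long sedentary stillness with sleep by
construction: a 20-hour motionless fixture yields a 20-hour "sleep"
period.  This is asserted in the tests as detector behavior, not as a
claim about true sleep.

30-s sleep states are the majority vote of the six 5-s inactivity flags
(ties to sleep; epochs with ≥ half invalid flags are invalid).  The SRI
for the day-pair (k−1, k), stored on day k, is `200·agreement − 100`
over jointly valid epochs and is missing when the jointly valid
fraction is ≤ 0.8.

*Low variation* is a separate stillness measure: the per-minute average
over axes of the mean absolute successive sample difference, below a
threshold for ≥ 5 min.  No published threshold exists (it was chosen by
visual inspection in the source work); the default 0.01 g per sample
interval was calibrated on synthetic sleep fixtures and is **not** a
literature value.

## Daily features and validity

M10/L5 are sliding-window means of minute activity (10 h / 5 h windows
constrained within the calendar day, no midnight wraparound; earliest
start wins ties).  Non-worn minutes are excluded from window means and
windows with more than 25 % missing minutes are skipped.  RA =
(M10 − L5)/(M10 + L5).  Intensity classes use lower-inclusive cut-points
at 40/100/400 mg (configurable — wrist placement was participant-chosen
in the emulated design, so between-person comparability is limited);
MVPA is plain time above the moderate cut-point with no bout criterion.
The temperature rhythm is a least-squares cosinor
`T(t) = M + A·cos(2π(t − φ)/24)` on worn minutes (≥ 50 % required),
with amplitude ≥ 0 and acrophase in [0, 24); constant input gives
amplitude 0 and a missing acrophase.

PA fields are masked when midnight-anchored wear < 75 %; sleep fields
when noon-anchored wear < 75 %; SRI additionally requires its day-pair
validity > 0.8.

## PROM scoring

Diary de-duplication prefers entries submitted between 5 pm on the
associated day and 5 am the next morning ("correct") over entries
anywhere on the associated or following day ("feasible"); among equals
the earliest submission wins (a tie rule the source leaves open);
entries outside both windows are dropped.  Global pain is the mean of
the two pain items (1–10); global BFI the mean of the nine fatigue
items (0–10), missing unless all nine are present.  EHP-30 items (0–4)
map to subdomains by the published instrument layout (pain 11, control
6, emotion 6, social 4, self-image 3 — supplied as a table so
alternative layouts can be passed); each scale is
`100 · sum(items) / (4 · n_items)`.  By default no missing items are
tolerated per scale (configurable).

## Cycle summaries

Per cycle (or participant) and variable: mean (≥ 10 non-missing days),
then SD, adjusted Fisher–Pearson skewness, quartiles, IQR and the means
of the upper/lower quartile of daily values (each ≥ 20 days).  "Mean of
the upper quartile" means the mean of the ⌈n/4⌉ largest values — the
count convention was open and is configurable.  TKEO and RMSSD are
computed on the series after linear interpolation of interior gaps of
≤ 3 consecutive missing days (longer and edge gaps stay missing),
residual missing removed.  Both divide by N exactly as printed in the
source formulation although the sums have N−2 and N−1 terms; a
`conventional=True` flag offers the textbook normalization for
comparison.  Adherence over days 1–28 of a cycle: diary adherence =
submitted days / 28, watch adherence = days with > 75 % wear / 28,
weekly breakdowns, cycles kept when more than one diary entry exists or
smartwatch data was returned; shorter cycles use available days and are
flagged.

## Association models

**Repeated-measures correlation** uses the ANCOVA formulation (subject
as factor, common slope), implemented directly rather than delegated so
that the brute-force design-matrix oracle in the tests is a genuine
cross-check: r is the correlation of within-subject-centered x and y,
df = n_obs − n_subjects − 1, p from the F-ratio on (1, df).
Pairwise-complete rows only; subjects need ≥ 2 pairs.

**Intra-person correlations** are per-participant Pearson coefficients,
reported only with ≥ 20 complete pairs; constant-input participants are
excluded with a reason.

**Partial correlations** come from the inverse correlation matrix:
`r_ij·rest = −P_ij/√(P_ii·P_jj)`; the Spearman variant ranks first.
Complete cases are required (k + 2 rows minimum) and singular matrices
raise an error naming collinear columns.

**The daily symptom mixed model** regresses the global BFI (or global
pain) on the other symptom score, same-/previous-day M10, same-/
previous-night sleep duration and WASO, and the sleep regularity index,
with a participant random intercept and continuous-time AR(1) residual
correlation `corr(ε_a, ε_b) = φ^|day_a − day_b|` indexed by study day —
chosen over a lag-index AR(1) because diary days are irregularly
missing.  All variables are z-standardized over included rows (global,
not per subject).  Rows missing any variable are dropped; previous-day
covariates require an actual adjacent day, so the first day of each run
is dropped rather than imputed.  Estimation is REML: the profiled
objective over (log σᵤ², log σₑ², tanh⁻¹ φ) is minimized with
Nelder–Mead; per-subject covariance blocks are small (≤ cycle length)
so direct Cholesky solves are used.  Non-convergence is flagged, never
silently replaced.  The implementation reproduces R `nlme::lme` with
`corCAR1` to ~1e-3 in the fixed effects on test fixtures.

**Cycle-level associations** are Spearman (optionally partial)
correlations across cycle summaries with a "strong" flag at |R| > 0.3.
No multiple-comparison adjustment is applied, matching the exploratory
stance of the design; the output metadata states this.

**Surgical change**: each daily measure is min-max scaled over all daily
data from all participants (constant measures become missing); the
per-participant delta is the mean over post-op days 1–10 minus the mean
over the baseline (first) cycle; participants with < 3 post-op points
are excluded with a reason; the cohort trajectory keeps only post-op
days covered by ≥ 50 % of participants.

## Synthetic cohort generator

Defaults mirror the emulated study design: 68 participants, three
28-day cycles, a 28-day symptom period, diary missingness 0.2 (≈ 80 %
observed adherence), fatigue–activity coupling −0.35, and a 1 Hz signal
layer (10 Hz supported; 1 Hz keeps testing at desk scale).

*Latent layer.*  Daily fatigue = phenotype baseline + sinusoid (symptom
period) + AR(1) noise (ρ = 0.5) + flare impulses (flare phenotype:
~1/14-day rate, +3 jump, 2-day decay — no quantitative description of
flare shape exists in the source, so these are free, documented
parameters).  Pain is affine in standardized fatigue with independent
noise, targeting a within-person pain–fatigue correlation of ≈ 0.67.
The activity dial is exact by construction: `activity_z = c·fatigue_z +
√(1 − c²)·noise` yields a within-person activity–fatigue correlation of
c without any calibration loop (an iterative bisection calibration was
considered and rejected as needless).  The post-surgical phenotype
halves activity at the surgery day with linear recovery over 20 days
and adds a decaying pain/fatigue spike.  Diary items are rounded and
clamped to their ordinal scales; the EHP-30 is driven by the upper
quartile of the cycle's latent symptoms (mirroring the tendency of
retrospective reports to reflect worst symptoms).  Missingness is MCAR
by default.

*Signal layer.*  Nightly sleep windows (23:00–07:00 with 30-min onset
jitter) have a stable arm angle and a 0.0015 g noise floor; wake
orientation jumps minute-to-minute; wake movement noise is scaled by
the day's latent activity (multiplier calibrated so daytime minute ENMO
lands on the latent activity scale).  Wear temperature is ~30.5 °C with
a 1.2 °C diurnal rhythm peaking at night (distal skin temperature rises
during sleep) plus a slow drift.  Injected non-wear freezes the
orientation at the sensor noise floor and relaxes temperature toward
ambient (21 °C) with a 5-min time constant, re-warming with a 3-min
constant.  The cooling constant must satisfy `0.5·τ ≤ T1_cap − ambient`
(≈ 6 min here) for the drop-rate and absolute-threshold criteria to
produce one contiguous candidate run — a slower sensor would break the
short-pass 2 °C filter; small wrist sensors cool on this scale.

*What passing tests do not show.*  The generator has no device noise
spectra, no naps or multi-period sleep, no menstrual hormone
physiology, no posture-specific orientation statistics, and its
non-wear density is in the detector's reliable regime.  Detector and
estimator accuracies on these fixtures therefore bound idealized, not
clinical, performance.

## Problem sizes used in the standard checks

Detector recovery uses 10 recordings × 7 days at 1 Hz; coupling
recovery uses 30 participants × 28 days over 20 seeds (latent layer);
mixed-model recovery uses 50 replicates of 40 × 28; the end-to-end run
uses 3 participants × 14 days at 1 Hz.  These sizes give stable
estimates at desk scale while exercising every code path.
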