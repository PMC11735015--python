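# Methods

This note documents the statistical model behind `hragree`, the frozen
conventions in each pipeline stage, the design of the synthetic
paired-signal generator, and the package's known limitations. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model

A *session* is a pair of timestamped heart-rate series recorded
simultaneously by a test device (wrist PPG) and a criterion device
(ECG chest strap), plus metadata (participant, activity from the closed
vocabulary {badminton, tennis, orienteering, run, bike, soccer},
Fitzpatrick skin tone 1–6). Analyses are stratified by activity and by
the pooled groups racket = {badminton, tennis} and running sports =
{orienteering, run}; pooling is sample-level (statistics are computed
on the concatenated per-second samples, never by averaging per-session
statistics).

On read, timestamps are normalized to seconds from the first sample —
all downstream mathematics is relative, and the lag search absorbs any
wall-clock offset. HR values outside the open plausibility window
(20, 250) bpm are dropped (not clamped) with a logged count; there is
no other pre-cleaning.

## Synchronization

Order of operations, frozen: resample → lag → intersect → smooth.

* **Resampling**: linear interpolation onto integer seconds within the
  native span (no extrapolation). Native gaps longer than `max_gap`
  (default 30 s) are left missing and the affected grid points are
  excluded from the aligned overlap. Linear interpolation is the
  simplest defensible choice; HR is near-piecewise-linear at the 1 s
  scale.
* **Lag search**: exhaustive over integer lags in ±`max_lag`
  (default 120 s, generous for start-button offsets), minimizing the
  mean squared difference over the overlap; a positive lag means the
  test stream trails the criterion. Ties break toward smaller |lag|,
  then toward the negative lag. 1 Hz data cannot resolve sub-second
  lag, so no sub-grid refinement is attempted.
* **Smoothing**: centered moving average over the `smooth_window`
  (default 10 s). Even windows are widened to the next odd point count
  (10 s → 11 points, ±5 s) so the window stays centered; at the series
  edges the window truncates to the available samples. Smoothing is
  applied after lag correction, to both series symmetrically, so it
  cannot bias the differences. Whether the original procedure smoothed
  before or after lag estimation, or used block averaging instead of a
  moving average, is not determinable; these choices are frozen here.

All agreement statistics and artifact flags are computed on the same
smoothed `AlignedPair` — one source of truth.

## Artifact definition

A sample is an artifact when |test − criterion| strictly exceeds the
threshold (default 20 bpm) on the smoothed pair. The boundary
convention (strict `>`) is frozen but configurable. Flagged samples are
**not** removed from the agreement statistics by default; exclusion is
an explicit opt-in (`exclude_artifacts`), and the artifact percentage
always refers to the full sample.

## Agreement statistics

Sign convention: d = test − criterion, so a negative bias means the
wrist device underestimates.

* **Bland–Altman**: bias = mean(d); SD uses the n−1 sample estimator;
  upper/lower LOA = bias ± 1.96·SD; width = 3.92·SD.
* **MAE / MAPE**: means of |d| and 100·|d|/criterion, each reported
  with its across-sample SD (whether such SDs should be across samples
  or sessions is ambiguous in the field; across samples is frozen).
* **ICC(2,1)**: single-measure, two-way random-effects, absolute
  agreement (McGraw & Wong A,1), with subjects = time samples and
  raters = the two devices — the only reading that yields one ICC per
  activity from time-series data. Absolute agreement is the relevant
  estimand for device interchangeability because a constant offset
  between devices lowers it; a consistency variant ICC(3,1) is exposed
  behind `icc_variant="consistency"`. The 95% CI uses the standard
  F-distribution construction with the Satterthwaite degrees of
  freedom; the implementation is verified in the tests against an
  independent from-definition ANOVA oracle (1e-10) and against
  pingouin's ICC(A,1) row.
* **Lin's CCC** with 1/n moment estimators, per the original estimator.
  Degenerate conventions: two equal constant series → 1 (with a
  warning); constant vs varying → 0.
* **Qualitative bands**: ICC poor/moderate/good/excellent at
  0.5/0.75/0.9; CCC poor/moderate/very good/almost perfect at
  0.90/0.95/0.99. The conventional strict-inequality phrasing leaves
  the cut points unassigned; here a value exactly at a cut belongs to
  the **higher** band (0.75 → good, 0.95 → very good).

No autocorrelation correction is applied to the LOA or to the ICC CI.
1 Hz HR differences are strongly autocorrelated, so these intervals
are anti-conservative; this mirrors standard practice in wearable
validation studies and is a known limitation, not an option.

## Cohort statistics

* **Normality**: one-sample Kolmogorov–Smirnov against a normal with
  the sample's own mean and SD, i.e. the Lilliefors construction
  (statsmodels implementation; plain KS tables would be strongly
  anti-conservative with estimated parameters).
* **Across activities**: Kruskal–Wallis with tie correction on the
  per-sample differences grouped by activity (the sample level, not
  per-session biases, is the unit of analysis).
* **Bias vs zero**: the scientifically sound construction for a
  one-sample question is the Wilcoxon signed-rank test on the
  differences (reported statistic: W+, the positive-rank sum); a
  literal two-sample Mann–Whitney U of the differences against an
  equal-size all-zeros sample is available as
  `method="mannwhitney-vs-zero"` for fidelity with reports phrased
  that way.
* **Skin tone**: OLS of per-session Bland–Altman bias on the numeric
  Fitzpatrick score plus activity indicators (reference level = first
  activity alphabetically). With one activity the model reduces to
  simple regression. Rank-deficient designs raise an error naming the
  columns.
* No multiple-testing correction is applied anywhere, matching the
  practice the pipeline emulates.

## Synthetic paired-signal generator

The generator emulates the error structure that the analysis assumes,
so every stage can be tested end to end:

* **True HR**: piecewise activity targets approached with a first-order
  exponential (time constant 30 s), plus a stationary
  Ornstein–Uhlenbeck perturbation (default SD 5 bpm, timescale 60 s),
  clipped to (40, 220) bpm.
* **Criterion stream**: truth + white Gaussian noise (default SD
  1 bpm) at 1 Hz.
* **Test stream**: truth delayed by a constant integer lag (default
  7 s), plus a constant device bias and white Gaussian noise in the
  normal state. A two-state Markov chain (per-second enter/exit
  probabilities, started from its stationary distribution) switches
  into an artifact state during which the device holds truth plus a
  plateau offset drawn once per burst — the "sudden uncoupling"
  signature of wrist PPG under sharp arm movement. The test stream can
  be emitted at a coarser period (generic default 5 s, to exercise
  resampling; activity presets use 1 Hz, the native rate of the
  emulated devices). Both emitted series are rounded to 0.1 bpm.

### Preset calibration

Each activity preset is derived from three per-activity design targets
(Bland–Altman bias B, LOA width W, artifact percentage A; stored with
the reliability reference values in `activity_presets.yaml`) by
closed-form design arithmetic:

1. **Offsets centered on the bias.** Per-burst offsets are uniform on
   B ± h. Centering makes the session mean equal B for *any* burst
   occupancy, so occupancy fluctuations cannot move the recovered
   bias; the normal-state bias also equals B.
2. **Raw-variance identity.** The normal-state difference SD σ_d
   (split as σ_d² = σ_test² + σ_criterion²) solves the mixture-variance
   identity against the raw difference SD (W/3.92)². The raw scale is
   the calibration target (it is also the scale on which the
   acceptance checks inject noise); since the pipeline smooths before
   measuring, the *measured* LOA width is narrower than W — a
   documented consequence of the 10 s smoothing, not an error. For a
   few activities (tennis, run) the (W, A) pair is attainable under
   the burst model only at the noise floor, where this identity holds
   approximately.
3. **Exact artifact-rate design.** The expected flagged fraction of
   the *smoothed* difference series is computed exactly under the
   generator model by enumerating all 2^11 artifact-state patterns an
   11-point smoothing window can contain, weighting each by its
   stationary Markov probability, with the per-burst uniform-offset
   expectation integrated in closed form (the integrand is nearly a
   step function when the within-window noise is small, where
   quadrature fails). This accounts for burst-edge smearing by the
   window, bursts shorter than the window, and Gaussian tail flags in
   the normal state. The enter probability is root-found so this
   expectation equals A, inside a damped fixed point that couples the
   occupancy back into the variance identity.
4. **Precision-optimal spread and burst length.** The offset
   half-range h and the burst exit rate are chosen per activity on a
   fixed grid by minimizing the *analytic* sampling SD of the
   recovered bias at n = 50,000 (white noise + occupancy
   autocorrelation + offset-draw contributions), preferring designs
   off the noise floor. The chosen constants are frozen in the preset
   file; the sweep (`design_offset_sweep`) is deterministic design
   arithmetic and never consults simulation output. The frozen designs
   predict a bias-recovery SD ≤ 0.13 bpm per preset at that n.

The emulated cohort composition (sessions and recorded hours per
activity: 55 sessions, 77.5 h in total; skin tones drawn from {2, 3, 4}
with weights 6/26, 17/26, 3/26, cohort mean 2.9) is also stored in the
preset file; `make_cohort` writes deterministic session-directory trees
from a single root seed with independent per-session streams.

### What the generator does and does not emulate

It reproduces: activity-dependent bias, noise and artifact-rate levels;
device clock lag; plateau-like artifact bursts; 1 Hz sampling and
0.1 bpm quantization; cohort structure. It does **not** reproduce:
beat-to-beat HRV structure (the OU term is a coarse stand-in),
autocorrelated (non-white) PPG tracking error outside bursts,
accelerometry, duty-cycle gaps in device output, any skin-tone effect
on signal quality (none is injected, so the skin-tone model's null
recovery on synthetic cohorts shows calibration, not field validity),
or the smoothed-scale LOA widths (see above). Passing tests therefore
demonstrate that the pipeline recovers known structure of this model
class, not that the model captures every property of field PPG data.

## Numerical choices and degenerate inputs

* Lag ties break toward smaller |lag|, then negative; the noiseless
  shift-recovery property is exact for any |lag| ≤ max_lag.
* A plain least-squares lag objective interacts with net HR drift when
  the device bias is large: the cross-term −2·bias·E[Δtruth] can move
  the optimum by ±1 s on short, strongly drifting sessions. This is a
  property of the (frozen) method itself; it is negligible for
  realistic session lengths and is exercised in the tests with
  drift-free profiles.
* Sub-grid emission (5 s test sampling) limits lag resolution to about
  one grid step after interpolation.
* Perfect agreement (zero within-sample variance) returns ICC = 1 with
  a degenerate CI (1, 1); negative ICCs are returned as computed,
  never clamped.
* With k = 2 raters, the single-measure ICC estimator's denominator
  contains a χ²(1)-distributed rater mean square; a large rater
  variance share makes the estimator visibly ratio-biased upward. The
  replicated-simulation checks therefore use a small rater share
  (0.1 of the non-subject variance) — the population ICC is unchanged.
* Report rounding: bias/LOA/width/MAE and percentages to 1 decimal,
  ICC/CCC to 3 decimals; JSON and CSV outputs always carry full
  precision, and the rendered tables are derived from the same values.

## Problem sizes

The test suite runs in well under a minute: oracle checks use ≤ 10-point
hand inputs; recovery checks use n = 50,000 one-second samples per
preset, 200 × 5,000 replicates for the ICC, and 50,000 pairs for the
CCC — sizes at which the Monte-Carlo error is several times smaller
than the assertion tolerances. `scripts/acceptance.py` recomputes the
three headline quantities at the same sizes from a single seed.
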