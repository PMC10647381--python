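# Methods

## Problem and pipeline

Time-domain HRV statistics are only meaningful on *NN intervals* — the
times between consecutive normal sinus beats. Ectopic beats, detector
artifacts, atrial fibrillation and sinus pauses all corrupt them, and the
corruption is strong enough to dominate cohort-level conclusions if left
in. The package therefore runs every recording through a fixed sequence:
screening → NN-segment extraction → windowed HRV → cohort aggregation →
dependency fits / normal-range estimation / classification. Each stage is
a pure function of its inputs (and a seed, where random), so every number
in the output is reproducible.

## NN cleaning

An interval qualifies only if both endpoint beats are labeled N; intervals
touching A, V, S, F, Q beats or an X artifact-span marker are rejected
outright. Between consecutive accepted intervals the strict relative-change
bound

    prev·(1 − a) < cur < prev·(1 + a),   a = `allowable_change` = 0.15

must hold. When it fails, the offending interval is discarded entirely and
the *next* interval seeds a new run without a comparison — a seed has no
accepted predecessor, so no bound can apply to it. Runs shorter than
`min_run` = 6 intervals are dropped. Both parameters are exposed: `a` can
be lowered for stricter cleaning, and the bound can be re-parameterized to
any other reading of a relative-change rule through `allowable_change`
alone. `min_run` counts intervals, not beats: every downstream formula
operates on intervals, so the run length that matters statistically is the
interval count.

Whole recordings are excluded when atrial fibrillation is flagged (HRV on
fibrillating rhythm is not interpretable) or when any interval reaches
`pause_ms` = 3000 ms, the conventional clinical cut-off for a sinus
pause/arrest.

The extractor is implemented with vectorized candidate masks plus a walk
over the (rare) bound violations; the test suite holds it equal to an
independent sequential re-derivation and to an O(n²) rule validator on
randomized labeled sequences with planted violations.

## HRV parameters

All standard deviations are *sample* (n−1 divisor) standard deviations —
the dominant convention in the HRV literature; fixing it lets the oracle
tests demand 1e−9 agreement. NN50 counts successive differences strictly
greater than 50 ms. SDANN/ASDNN partition a window into contiguous 5-min
bins by interval onset; bins with fewer than 2 intervals are skipped and at
least 2 qualifying bins are required, otherwise the parameter is reported
absent rather than guessed. Poincaré axes use the standard ellipse
identities SD1 = RMSSD/√2 and SD2² = max(0, 2·SDNN² − SD1²); the SD1/SD2
ratio is absent when SD2 = 0.

Two aggregation methods turn a window's clean segments into one value:

* **Average (A)** — the unweighted arithmetic mean of per-segment
  parameters, including the per-segment NN50 count (hence real-valued).
  Unweighted rather than length-weighted: the method is defined as the
  average *of the per-sequence HRV values*, and weighting would silently
  turn it into the Combined method as segments lengthen. SDANN/ASDNN are
  the exception: segments are routinely shorter than 5 min, so the 5-min
  definition is only well-posed on the window's pooled accepted intervals,
  and method A computes them there.
* **Combined (C)** — one computation over the concatenated segments.
  Successive-difference statistics (RMSSD, NN50, pNN50, SD1) skip the
  junction pairs between segments; a junction is exactly where the cleaning
  removed an artifact or ectopic run, and differencing across it would
  re-inject the jump the cleaning removed. Concatenating segments with
  different local means inflates C_SDNN relative to A_SDNN (the two-segment
  fixture: A_SDNN = 0, C_SDNN ≈ 102.6 ms), which is why the Average method
  is the default for dependency analysis.

Sliding windows are `[k·s, k·s + w)` for k = 0, 1, … while they fit, giving
`floor((span − w)/s) + 1` placements; membership is by interval onset in
the half-open window, so adjacent windows never double-count an interval.
Default offsets: s = 5 min for 30-min/2-h/8-h windows, s = 10 min for 24-h.

## Cohort statistics

Correlations are Pearson, Spearman (mid-ranks on ties) and point-biserial
(Pearson on a 0/1 code; gender is coded M=0, F=1, so a negative gender
coefficient means lower values in women). Group comparisons use Welch's
unequal-variance t-test, Mann–Whitney U with the asymptotic normal
approximation (tie and continuity corrections), and the asymptotic
two-sample KS test. These standard routines are delegated to scipy.stats;
the test suite pins each one to a from-scratch textbook implementation at
1e−12. Age-dependency functions are plain OLS fits `y = intercept +
slope·age` with the Pearson r/p of the fit.

Cohort correlations aggregate *per subject* first (each subject contributes
the mean of its window-level values per parameter). Overlapping sliding
windows produce thousands of highly dependent rows per subject; treating
them as independent observations would make p-values meaningless.
Per-window pooling remains available for exploration. No multiple-testing
correction is applied; raw p-values are reported together with n.

Age groups are <30, 30–40, 40–50, 50–60, 60–70, >70 with half-open
boundaries (70 falls in >70). The boundary convention is arbitrary but must
be fixed for group quantiles to be reproducible.

## Normal ranges and rank-based evaluation

Group quartiles use the median-of-halves rule — Q2 is the median, Q1/Q3 are
the medians of the lower/upper halves, the odd-n median excluded from both
halves — because the evaluation methodology is defined in terms of
"middle values", not interpolated quantiles (numpy's default linear
interpolation differs on small groups). Direct per-group quantile
estimation replaces any trained regressor here: with only 12 discrete
age-group × gender inputs, a universal approximator trained to convergence
reproduces the per-group statistics, so the lookup is the deterministic
equivalent; the classification harness accepts any scikit-learn-style
learner for experimentation.

A predicted range is scored against the measured group's reference
quartiles: the quartiles split the axis into four right-closed rank bins,
the predicted [Q1, Q3] spans a set of bins, and the single measured value
occupies one bin. TP = measured bin predicted; FP = predicted but not
measured; FN = measured but not predicted; TN = the rest — so the four
counts always sum to 4 per sample and aggregate additively. TPR/FPR/PPV and
F1 (harmonic mean of TPR and PPV, 0 when both are 0) follow. ROC-AUC uses
the Mann–Whitney pair-concordance identity with ties at ½; multiclass AUC
is macro one-vs-rest. The ND/GD/BD harness runs stratified k-fold CV
(default 10, reduced with a warning when the smallest class is smaller),
reports the pooled confusion matrix alongside per-fold macro F1 — the two
summaries answer different questions and need not agree — and headlines
macro F1 because the classes are strongly imbalanced.

## Synthetic cohort generator

The generator's job is to produce cohorts in which the quantities the
analysis estimates are *known by construction*:

* Subject targets: SDNN and RMSSD means follow the linear age-dependency
  functions per condition (healthy 60.62 − 0.49·age and 42.19 − 0.32·age;
  arrhythmia 44.30 − 0.13·age and 37.71 − 0.046·age, ms), a −2 ms SDNN
  offset for women (direction only; the magnitude is a config knob, not a
  claim), and i.i.d. Gaussian between-subject noise (default sd 5 ms),
  floored at 3 ms. BD-class subjects draw from the shallow-slope
  (arrhythmia-style) functions — synthetic-world ground truth chosen so the
  glucose-regulation harness has a detectable signal, not a physiological
  claim.
* RR stream: a stationary Gaussian AR(1) process with mean 800 ms, marginal
  sd = SDNN target, and lag-1 autocorrelation ρ = 1 − RMSSD²/(2·SDNN²),
  the unique value that moment-matches E[RMSSD²] = 2σ²(1−ρ). AR(1) is the
  minimal stationary process matching the two moments the analysis treats
  as primary, which keeps parameter recovery analytically checkable.
  Draws are clipped to [300, 2000] ms; at study-relevant variability
  (SDNN < 60 ms around 800 ms) the clipping is ≥ 4σ out and its bias is
  negligible (the moment-recovery test passes at 1%).
* Corruption: ectopic beats are injected per-beat with the configured
  probability (V or S, equiprobable), each shifted 30% early with the
  compensatory pause preserving the two-interval sum; adjacent hits are
  skipped so every ectopic stays locally time-conserving. Artifact spans
  arrive as a Poisson process (spans/hour), uniform 5–30 s long; beats
  inside are removed and X markers bound the gap. An AFIB-like recording is
  represented by the screening flag, since screened recordings never reach
  HRV computation.

What the generator does **not** model: respiratory sinus arrhythmia,
circadian rhythm, non-Gaussian RR distributions, or any within-subject
nonstationarity. Passing tests therefore demonstrate that the pipeline's
estimators recover the moments and trends the generator encodes — not that
real Holter data satisfy AR(1) assumptions.

## Problem sizes and numerical choices

The default study sizes used by the tests and the acceptance script:
moment recovery on 10⁵ intervals (1% tolerance, law-of-large-numbers
scale); single-cohort slope recovery with 200 subjects × 30-min records
(slope within 3 standard errors of the configured −0.49); the
healthy-vs-arrhythmia slope-ordering replication with 100 pairs of
40-subject cohorts — at that size the expected slope gap (0.36 ms/year)
exceeds its standard error several-fold, so the ordering is stable without
being trivially saturated. Oracle agreement tolerances are 1e−9 for HRV
formulas (float64 arithmetic on ms-scale values) and 1e−12 for the
correlation/test statistics.

Degenerate inputs are signaled, not guessed: fewer than 2 intervals, a
constant variable in a correlation, a single class in the classifier, or
fewer than 2 qualifying 5-min bins all raise or mark the value absent with
a reason code.

## Known limitations

* The WFDB annotation reader covers the common beat codes and pseudo-codes
  of the MIT format; exotic codes raise rather than guess, and multi-signal
  header subtleties beyond the sampling frequency are ignored.
* The Average method is unweighted; cohorts with strongly varying segment
  lengths may prefer a length-weighted variant, which is a three-line
  change on top of the per-segment values the module already exposes.
* The rank-bin universe for range evaluation is the four quartile bins;
  finer rank grids would need a different reference summary than Q1/Q2/Q3.
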