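# Methods

## The model

After a gadolinium bolus, the lesion-mean relative enhancement of a
dynamically acquired (GRASP-VIBE-style) perfusion series is described by a
modified Brix two-compartment model,

```
E(t) = A · k_ep · (exp(−k_ep t) − exp(−k_el t)) / (k_el − k_ep),
```

with dimensionless amplitude `A`, exchange rate `k_ep` (1/s, tissue → plasma)
and elimination rate `k_el` (1/s).  `E(0) = 0` by construction.  For
`0 < k_el < k_ep` the curve rises to a single peak at
`TTP = ln(k_ep/k_el)/(k_ep − k_el)` and then decays; for `k_el ≤ 0` it rises
monotonically through the whole acquisition window — the shape typical of
lesions that later show pathologic complete response.  At `k_el = k_ep` the
expression degenerates; within a relative gap of 1e−8 the analytic limit
`A·k_ep·t·exp(−k_ep t)` is used to avoid catastrophic cancellation (both the
value and the Jacobian switch to series-limit forms).

### Semi-quantitative features

All features are read off the *fitted* curve, not the raw samples:

* **PE** — maximum of `E` over the window; at the closed-form peak for
  `0 < k_el < k_ep`, at the window end for `k_el ≤ 0`.
* **TTP** (s) — the location of that maximum, clipped to the window.
* **wash-in / wash-out** (1/s) — maximum and minimum of `dE/dt` over the
  window.  `dE/dt` has at most one interior stationary point, at
  `ln(k_ep²/k_el²)/(k_ep − k_el)` (twice the TTP when `k_el > 0`), so the
  extrema are taken over {0, that point, window end}.  Note that for
  `k_el < 0` the *minimum* of the derivative also sits at that interior
  point (and stays positive), not at the window end.
* **AUC** (enhancement·s) — closed-form integral of `E` over a fixed early
  window.  The window defaults to **60 s** after bolus arrival: at the
  published group-median parameters the 60-s integral reproduces both
  published group AUC medians (≈78–85) to within a few percent, whereas
  full-window integration is ~5× larger.  This window is an inference, not a
  published definition, and is configurable (`auc_window`).

The evaluation window for PE/TTP/wash rates defaults to the last normalized
timestamp of each patient's curve (≈ 280–330 s after arrival).

## Preprocessing

The baseline `S0` is the arithmetic mean of the first five frames, assumed
pre-bolus.  Bolus arrival is the first frame whose raw intensity *strictly*
exceeds `1.05·S0` (the strict inequality is a choice; the boundary case is
measure-zero on real data).  Pre-arrival frames are dropped, the arrival
frame becomes `t = 0`, and enhancement is `(S − S0)/S0` (so `PE ≈ 2` means
the signal tripled).  A curve that never crosses the threshold is
unanalyzable and is excluded with a logged reason; a curve whose threshold
crossing falls inside the five-frame baseline window is rejected as having a
contaminated baseline.

Because enhancement needs ~0.5–3 s to climb from 0 to the 5 % threshold, the
detected arrival frame lags the true arrival by up to one frame interval.
The normalized curve is therefore a slightly time-shifted read of the
underlying kinetic curve — a property of the thresholding procedure itself,
shared with any acquisition analyzed this way.  It biases fitted parameters
by far less than measurement noise at the default settings.

## Fitting

`(A, k_ep, k_el)` are estimated by damped least squares: scipy's
trust-region reflective solver (Levenberg–Marquardt-type damped steps
honoring box constraints) with the analytic Jacobian, tolerances 1e−10
(cost and step), at most 1000 function evaluations, and box constraints
`A ∈ (0, 20]`, `k_ep ∈ [1e−4, 1]`, `k_el ∈ [−0.05, 0.05]`.  The objective is
multi-modal, so the solver is started from a fixed 3×3×3 grid
(`A ∈ {1,2,4}`, `k_ep ∈ {0.01,0.05,0.2}`, `k_el ∈ {−1e−3,1e−4,5e−3}`); the
start with the smallest residual sum of squares wins, ties broken by the
smaller `k_ep`.  The result is fully deterministic.  A test cross-checks the
bounded solution against unbounded MINPACK Levenberg–Marquardt on interior
noiseless truths.  Noiseless sampled curves across the published IQR ranges
refit to better than 1e−4 relative error in every parameter.

## Cohort statistics

* Group comparison: two-sample Mann–Whitney U, exact null distribution when
  both groups have ≤ 25 tie-free observations, otherwise the tie-corrected
  normal approximation; Kruskal–Wallis for ≥ 2 groups.  Holm adjustment
  across the parameter family is available but off by default, matching
  per-row reporting conventions.
* ROC AUC via the rank statistic (ties counted ½), with DeLong
  structural-component variance for the 95 % CI, and DeLong's test for
  comparing two correlated AUCs.  These are implemented from first
  principles; `sklearn.metrics.roc_auc_score` is used only as a test
  cross-check.
* Intrarater reliability: two-way absolute-agreement single-measure ICC
  (McGraw–Wong ICC(A,1), via pingouin) with an F-based 95 % CI.  The
  interpretation reports the range of agreement bands the CI spans
  (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent), e.g. a
  CI of (0.64, 0.98) reads "moderate to excellent".

## Response classifier

A random forest over 15 candidate predictors (`A`, `k_ep`, `k_el`, `TTP`,
`PE`, `AUC`, `wash_in`, `wash_out`, `T1_raw`, `T1_ratio`, `STIR_raw`,
`STIR_ratio`, `ADC`, `hpv_p16`, `age`), evaluated by repeated stratified
10-fold cross-validation (10 repeats by default).  Design choices:

* **SMOTE inside the CV loop.**  The minority class is oversampled to
  balance *within each training fold only*; every test-fold row is an
  original patient.  Applying SMOTE before splitting leaks synthetic
  neighbors of test points into training and overstates AUC; a switch
  (`smote_in_fold=False`) reproduces that optimistic ordering for
  comparison.  Synthetic rows are convex combinations of a minority row and
  one of its k = 5 (or fewer, if the class is tiny) nearest minority
  neighbors over the continuous features; the binary HPV column copies the
  seed row.
* **Forest settings.**  500 trees by default; the candidate-features-per-split
  tunable is selected from {2, 4, 8} by an inner 3-fold CV on AUC.
  Parallelism is an execution detail with no effect on results given the
  fixed seeds.  The test suite and calibration checks run a reduced
  configuration (50 trees, fixed 4 features per split, 1–2 repeats): null
  calibration and signal-recovery conclusions are insensitive to forest
  size at these sample sizes, and the reduced setting keeps the full suite
  fast.
* **Pooled metrics.**  Out-of-fold probabilities are pooled over all
  repeats × folds (n_repeats × n patients classification events).  AUC with
  DeLong CI, and sensitivity/specificity at the 0.5 cutoff with Wilson 95 %
  intervals, are computed over the pooled events; ties at the cutoff
  classify as response.  Pooling repeats is also what makes the interval
  widths comparable to published small-cohort reports.
* **Backward selection.**  Starting from all 15 features, the single feature
  whose removal maximizes pooled CV AUC is dropped; selection stops when no
  removal strictly improves AUC.  Selection is run once globally (with the
  full elimination trace logged), not re-run per fold.

## Synthetic cohorts

The generator emulates the study conditions: 22 patients (15 pCR / 7
residual tumor), frames every 2.5 s over 338 s, acquisition starting 8 s
before injection, and a contrast transit of 15–30 s (uniform) after
injection — guaranteeing ≥ 5 pre-arrival frames.  Kinetic parameters and
conventional features are drawn per group from two-parameter distributions
matched to the published group medians and IQRs:

* `A`, `k_ep`: lognormal (strictly positive, right-skewed), log-location
  `ln(median)`, log-scale `(ln q3 − ln q1)/1.349`;
* `k_el`: normal (the responder median is negative, so positivity must not
  be enforced), mean = median, sd = IQR/1.349;
* T1/STIR raw and ratio values, ADC (10⁻⁶ mm²/s scale), age: normal fits to
  the published quartiles, resampled if a draw is non-positive;
* HPV-p16: Bernoulli with p = 10/22.

Raw curves are `S0` before arrival and `S0·(1 + E(t − t_arrival))` after,
plus zero-mean Gaussian noise of sd `0.01·S0`.  Gaussian (not Rician) noise
is a deliberate high-SNR simplification.  Baseline intensity is lognormal
around 300 arbitrary units with 10 % log-scale — the acquisition's raw
units are arbitrary and cancel in normalization, so only the noise
*fraction* matters downstream.  Arrival-transit and baseline statistics are
plausible defaults, not published values.

What the generator does *not* emulate: voxel-level heterogeneity and
partial-volume effects, motion, arterial-input variability, Rician noise at
low SNR, and any correlation structure between kinetic and conventional
features beyond their group membership.  Passing tests therefore show that
the pipeline is correct and well calibrated under the published group-level
distributions — not that the classifier's performance would transfer to
real patients.

## Numerical conventions and degenerate inputs

* Degenerate `k_el = k_ep` handled by series limits (model, derivative,
  integral, TTP = 1/k_ep).
* Perfect-agreement ICC short-circuits to 1 (the F statistics are
  undefined); zero between-subject variance raises.
* Training folds missing a class (possible at these group sizes) are
  skipped; pooled metrics remain defined because every patient still
  appears in test folds.
* All stochastic components route through one `numpy` Generator per entry
  point, so fixed seeds give bit-identical cohorts, fits and artifacts.

## Problem sizes used in the checks

Recovery checks use noiseless 3×3×3 parameter grids and 1000 noisy
replicates (enhancement sd 0.02) at the residual-tumor median truth;
calibration checks use 100 label permutations of one 22-patient cohort and
25 independent calibrated cohorts; Monte-Carlo quantile checks of the
quartile-fitted distributions use 10⁴–10⁶ draws.  These sizes are the
package's standing evaluation configuration.

## Known limitations

* The AUC integration window (60 s) is inferred from internal consistency,
  not from a published definition.
* The bolus-arrival threshold rule introduces a sub-frame time-shift bias
  (see Preprocessing).
* Sensitivity/specificity are pooled-CV quantities; a refit-on-all-data
  convention would give different (more optimistic) numbers.
* With 22 patients, cross-validated performance estimates carry wide
  sampling error regardless of pooling; the synthetic cohorts inherit that
  property by design.
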