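# Methods

This note records the scientific and numerical choices behind the
package: what each stage assumes, which constants matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## 1. From ECG to NN intervals

**Denoising.** A 4th-order Butterworth low-pass at 50 Hz (zero-phase,
forward–backward, so R-peak latencies are not shifted) removes mains and
EMG noise. A 9-level periodized db8 wavelet decomposition then zeroes the
level-9 approximation — at 200 Hz this carries content below ≈0.2 Hz,
i.e. baseline wander — and soft-thresholds the two finest detail levels
with the universal threshold σ√(2 ln n), σ estimated by the median
absolute deviation of the finest details. The DC level is restored after
reconstruction: the policy removes *wander*, not the mean. The wavelet
transform is implemented in `_wavelet.py` (PyWavelets is not a
dependency); it is the exact orthogonal periodized transform, verified by
a perfect-reconstruction property test.

**R-peak detection.** A Pan–Tompkins-style chain: band-pass 5–15 Hz,
derivative, squaring, 150 ms moving-window integration, peak picking with
a 200 ms refractory period and an adaptive height threshold (8% of the
99th percentile of the integrated signal), then refinement of each
candidate to the local band-passed maximum. An absolute 10 µV amplitude
floor prevents "detections" in flat or signal-free records. Against
planted beats the detector recovers 100% of beats within ±10 ms at 10 dB
SNR on the synthetic waveforms used in the tests.

**NN artifact filter.** Intervals outside 300–2000 ms, or deviating more
than 20% from the running median of the previous 5 accepted intervals,
are dropped (never interpolated). This is conservative: it also rejects
genuine beats during violent rhythm changes, which is acceptable for
5-min segment statistics.

**Segmentation.** Non-overlapping 300 s windows, restarted at each
protocol-stage onset so every segment lies in exactly one stage and
carries that stage's RPE. Segments with fewer than 100 beats are skipped
with a warning.

## 2. The feature battery

Time-domain definitions follow the conventional forms; two choices were
open and are fixed here: SDNN (and the chunk statistics) use the sample
standard deviation (n−1), and NN50 counts successive differences
*strictly* greater than 50 ms. SDANN/SDNNi chunk the window into 60 s
spans by onset time; chunks with fewer than 2 beats are excluded from
SDNNi, and both are reported missing when fewer than 2 usable chunks
exist.

The geometric pair uses a histogram with 1/128 s ≈ 7.8125 ms bins,
half-open and anchored at 0 ms. HRVTi = n / modal count. TINN fits a
triangle with apex fixed at the modal bin (center, height), searching the
baseline endpoints M, N exhaustively over bin centers left/right of the
mode (plus one bin beyond each flank) to minimize the squared difference
to the histogram; a single-occupied-bin histogram degenerates to
TINN = 0.

Frequency features use the Lomb–Scargle periodogram of the tachogram
(interval value vs. interval onset), mean-subtracted and *not* resampled
— the estimator is chosen precisely because NN series are irregularly
sampled. The grid is uniform, 0.0033–0.4 Hz in 1 mHz steps (397 points),
resolving band edges and peaks to the tolerance used in the tests. The
raw periodogram is scaled by 2T/N so that its integral approximates the
variance of the mean-removed series (ms²); with this convention total
band power lands within [0.5, 1.1]× the series variance, the deficit
being leakage below 0.0033 Hz. Band edges are half-open: 0.04 Hz belongs
to LF, 0.15 Hz to HF. A zero HF power leaves LF/HF missing, not infinite.

Nonlinear features: sample entropy with m = 2, r = 0.2 × the segment's
population SD (the conventional HRV defaults; the source protocol does
not state them), using the standard convention in which both template
lengths start at the same n−m positions — so a strictly periodic series
has entropy exactly 0. Poincaré SD1/SD2 are population SDs of the
rotated successive-pair coordinates; SD2 below 1 ns is treated as zero
and the ratio reported missing. DFA integrates the mean-removed series
and detrends linearly in non-overlapping boxes of 12 log-spaced sizes
between 4 and 64 beats, α₁ fitted on 4–16, α₂ on 16–64, α on the full
range — the standard short/long split for 5-min records. Monte-Carlo
checks recover α ≈ 0.5 for white noise and ≈ 1.5 for a random walk.

Missing values (zero-variance inputs, empty template counts, zero
fluctuations) propagate as NaN and are median-imputed at model-fitting
time from training folds only.

## 3. Null-importance feature selection

The selector's score is rank-based: the percentage of T label-permuted
refits whose Gini importance falls strictly below the actual importance.
Ties count against the feature. Because the score only compares ranks
within one feature, it is invariant to any global normalization of the
importances; we accumulate the *unnormalized* impurity decrease over all
split nodes and trees so that actual and null fits are compared on the
same scale.

Two under-specified points are fixed as follows:

- **Threshold semantics.** "Score lower than r1" with the default r1 = 0
  is unsatisfiable under a strict inequality, so the rule is score ≤ r1:
  r1 = 0 drops exactly the features whose actual importance never beats a
  single null draw.
- **Redundancy processing order.** Pairs with |r| > r2 are processed in
  descending |r|; a pair is skipped when either member was already
  removed, so a feature is never dropped for correlating with an
  already-removed feature. Importance ties drop the feature appearing
  later in the canonical feature order, making the output deterministic.

The forest configuration (100 trees, √m features per split, unlimited
depth, fixed seed) is identical for the actual fit and every null fit;
only the labels change. One behavioral consequence worth knowing: with
fully grown forests the total impurity decrease is similar under true and
permuted labels, so a *duplicated* informative feature — whose credit is
split with its twin — can occasionally score 0 and be dropped at the
unimportance stage before redundancy pruning sees it. Exactly one member
of each duplicated pair still survives to the selected set; the tests
assert that invariant.

Correlations involving a zero-variance column are undefined and treated
as 0, so they can never trigger pruning.

## 4. Classification and evaluation

Four families behind one interface: decision tree (Gini, unlimited
depth), SVM (RBF, C = 1, standardized inputs), KNN (k = 5, Euclidean,
standardized inputs) and a histogram-based gradient-boosted tree ensemble
(100 rounds, learning rate 0.1 — the LightGBM algorithm family, provided
by scikit-learn's implementation). Median imputation and, where used,
standardization are fitted on training folds only.

Cross-validation is grouped by subject: distinct subjects are randomly
partitioned into k = 10 folds of near-equal size (a fixed seed makes the
assignment reproducible; with 80 subjects every test fold holds exactly
8). Metrics are computed per fold and averaged (mean ± sd), with
confusion counts pooled over folds (rows = true class). Precision/recall
with a zero denominator are set to 0 with a warning — conservative, and
NaN never propagates into macro averages. Overall accuracy is
correct/total; macro precision/recall/F1 are unweighted means of the
one-vs-rest per-class values. No class rebalancing is applied: the
cohorts are imbalanced toward *Rested* and the evaluation should reflect
that.

## 5. The synthetic cohort

The generator stands in for a non-public treadmill study and emulates its
*structure*, not its physiology in detail. Each subject draws a resting
mean NN (Normal(850, 80) ms clipped to [600, 1200]), a fitness scalar
(Beta(2,2)), a variability multiplier (LogNormal(0, 0.25)) and an
exhaustion threshold (Normal(1.1, 0.12), floor 0.9). During a session a
latent fatigue state accrues at 0.007 × speed(km/h) / (0.5 + fitness) per
minute over the modified Bruce stages (0, 3, 5, 6.4, 7.8, 10.2,
11.6 km/h; the final stage runs until exhaustion, capped at 15 min). The
accrual constant places a median subject at the *A bit tired* boundary
around the third exercise stage and near exhaustion during the fifth or
sixth — the qualitative pattern reported for such protocols — and was
fixed before any classifier was run; the resulting gradient-boosting
accuracy (~0.85 on default settings) was an outcome, not a target.

Beat by beat, the NN interval is a fatigue-shrinking mean (baseline ×
(0.40 + 0.60 e^(−1.6 f))) plus LF (0.1 Hz) and HF (0.25 Hz) sinusoidal
modulation whose amplitudes decay at different rates (HF faster, so LF/HF
rises with fatigue) plus white jitter. RPE is reported at each stage end
as round(6 + 14·min(f, 1) + Normal(0, 0.8)), clipped to [6, 20] and made
non-decreasing; the reporting noise is what makes the *A bit tired* /
*Tired* boundary genuinely ambiguous.

What a green test on this cohort establishes: the pipeline's plumbing,
the feature math (including the structural near-identities meanHR ≈
60000/meanNN, SD1 = RMSSD/√2, 2·SDNN² = SD1² + SD2² that make the
redundant pairs emerge unforced), the selector's ability to recover
planted signal and calibrate its null, and leakage-free grouped
evaluation. What it does not establish: performance on real exercise ECG
— real morphology, ectopy, electrode artifacts, and real autonomic
dynamics are all absent.

`render_ecg` exists only to exercise the ECG front end: it paints a
symmetric QRS-like template (1 mV Gaussian R wave, σ = 10 ms, with small
Q/S dips) at the cumulative beat times, padding 0.25 s of baseline at
each end so edge beats have complete templates, and optionally adds white
noise at a requested SNR. Ground-truth beat indices are returned for
round-trip tests.

## 6. Scaling choices in the test suite

Property tests that repeat model fits are scaled to keep the default
suite fast without weakening the property: the planted-recovery test runs
T = 15 permutations with 50-tree forests (the partition and
pair-resolution invariants are T-independent), and the null-calibration
test replicates a small pure-noise dataset (n = 60, 3 features, 10-tree
forests, T = 30) 200 times — the uniformity of the rank-based score on
its T+1-point lattice holds for any forest size. The full-scale planted
check (n = 1000, effect size 3, T = 100) runs once in the acceptance
suite.

## 7. Known limitations

- WFDB and other binary ECG formats are not read; inputs are plain CSV
  (ECG samples or NN intervals).
- The QRS detector is tuned for the synthetic template and clean-ish
  single-lead ECG; pathological morphologies (bundle-branch block, pacing
  spikes) were never in scope.
- TINN's exhaustive (M, N) search is exact for the 1/128 s binning but
  O(b²) in the number of occupied bins; for 5-min segments this is
  negligible.
- The Lomb–Scargle normalization targets band-power *ratios* and peak
  locations; absolute ms² powers depend on the 2T/N convention and should
  not be compared across implementations without checking theirs.
- Sample entropy is O(n²) in beats per segment — fine at 5 min, not meant
  for hour-long records.
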