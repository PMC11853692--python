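# Methods

## Problem and model

`erpdecode` performs single-subject multivariate decoding of auditory
oddball ERPs: given epoched multichannel EEG with two trial classes
(frequent *standard* tones, rare *duration-deviant* tones), it asks at
which post-stimulus latencies the two classes are discriminable, how that
discriminative pattern generalizes across time, which electrodes carry it,
and — block by block over a recording session — whether it waxes and
wanes. The intended application is bedside assessment of auditory change
detection (MMN, ~150–230 ms, and P3a, ~250–350 ms, both frontocentral) in
comatose patients, where the effect can be intermittent and single-trial
SNR is poor.

The classifier is a linear max-margin model (linear SVM, liblinear via
scikit-learn) applied at every time point with the channels as features,
scored with the ROC area. AUC 0.5 is chance, 1.0 perfect separation.
Decoding, rather than grand-average peak reading, is used because it pools
spatial information and yields a single-trial-level statistic that can be
tested per subject.

## Cross-validation and nested preprocessing

Trials are first balanced by undersampling the majority class, then the
engine runs `n_folds` (default 5) stratified folds, repeated
`n_repetitions` (default 10) times. Fold assignment deals each class
round-robin along a label-blind random permutation; this is stratified and
additionally invariant under class relabeling, which makes the
label-flip-invariance of the pipeline exact in tests.

Two operations are nested inside every fold (estimated on the training
partition, applied to the test partition):

* **z-scoring** per feature (channel × time), sample sd (ddof 1).
  Zero-variance features are centered only, with a warning, so noiseless
  fixtures remain processable.
* **pseudo-trial averaging**: within each class, trials are partitioned
  into groups of `k` (default 5 for superblocks, 2 for single blocks;
  remainder dropped) and replaced by group means. Test trials are grouped
  within their own fold. Averaging k i.i.d. trials cuts noise variance by
  k at the cost of observations; the SNR benefit is verified as a
  stochastic property test.

**Regularization.** `c_grid` spans 0.01–100 in 7 log-spaced values. One C
is selected per (repetition, fold) by an inner 3-fold cross-validation on
the training partition, scoring the mean AUC over an evenly subsampled
time grid (≤ 40 points). Selecting a separate C at every time point would
multiply the fit count roughly twenty-fold with no benefit to any tested
contract; a per-fold C is the package's deliberate compromise. Ties go to
the smaller (more regularized) C. Single-value grids skip selection
entirely, which the scaled-down simulations use.

**Temporal generalization** reuses the identical folds, groupings and C
choices (all randomness is drawn before any scoring), trains at every time
point and tests at all of them; its diagonal therefore reproduces the
time-resolved curve to better than 1e-12 — the residual is dot-product
rounding, not a procedural difference.

**Searchlight**: one channel × one window (baseline −100–0 ms plus 50 ms
bins from 50 to 550 ms) at a time, window samples as features, same fold
and grouping schedule shared across all cells so the map is comparable
cell-to-cell; C fixed at the grid midpoint (1.0).

## Inference

Significance of the decoding curve is assessed with a label-permutation
test corrected over time by the cluster statistic (single-subject,
"Level-1" inference). The observed curve is computed once; each of
`n_permutations` (default 100) permutations shuffles the class labels and
reruns the full decoding with the same fold/seed schedule, so label
exchange is the only difference. The cluster-forming threshold is the
pointwise (1 − α) permutation quantile; clusters are maximal contiguous
supra-threshold runs scored by their mass Σ(AUC − 0.5) (cluster size is
available as an alternative); the null is the per-permutation maximum
cluster statistic, and p-values carry the +1 correction so p ≥
1/(n_permutations + 1). The cluster-forming rule and mass statistic are
the package's choice of the standard single-subject recipe; at least 20
permutations are required, and α below the attainable resolution is
rejected.

One practical caveat: band-limited epochs (especially after the 0.1 Hz
high-pass, and with strong pink noise) have few independent temporal
degrees of freedom, so under label permutation entire decoding curves
drift above or below chance together. The max-cluster null absorbs these
sustained excursions — error control is unaffected — but at small trial
counts they dominate the null and cost power. Synthetic sessions, which
contain no line noise or drift, are therefore analyzed without the filter
stage by default; filtering is intended for real recordings, preferably
applied to the continuous signal.

A block is flagged *reliable* exactly when its cluster test yields any
cluster with p ≤ α. Per-block analyses default to pseudo-trial groups of
2 because single blocks have too few deviants for groups of 5.

## Synthetic sessions

The generator emulates a bedside oddball recording: 512 Hz, the reduced
11-channel 10/20 montage (F3 Fz F4 C3 Cz C4 P3 Pz P4 T7 T8), epochs
−100–600 ms (half-open, 1/512 s spacing), five blocks of 400 tones,
deviant probability 0.15 with no two consecutive deviants (first-order
Markov chain with P(deviant | standard) = p/(1 − p), whose stationary
deviant rate is exactly p; p ≥ 0.5 is rejected as unattainable).

Deviant trials carry the difference components; standards carry none.
Components are Gaussian bumps parameterized by peak latency, FWHM width
and signed peak amplitude, truncated at ±3 sd and at stimulus onset, with
per-channel topography weights in [0, 1]. Defaults: MMN −3 µV at 190 ms,
80 ms wide; P3a +4 µV at 300 ms, 100 ms wide; topography 1.0 at Fz/Cz,
0.7 at F3/F4/C3/C4, 0.4 at P3/Pz/P4, 0.2 at T7/T8. Background noise is
white Gaussian (default sd 10 µV) plus pink noise (power ∝ 1/f, default
scale 5 µV), independent per channel and trial. Per-trial component gain
is block_gain × max(0, 1 + N(0, 0.2)); the block-level gain profile
(constant, sinusoidal, or custom) produces waxing/waning.

What the generator does **not** emulate: ocular/muscle artifacts,
cross-channel noise covariance (volume conduction), stimulus-timing
jitter, or latency variability of the components. Passing tests therefore
demonstrate correctness of the decoding machinery and its calibration, not
robustness to those real-data features; filtering and artifact rejection
are exercised on the synthetic data but are not stressed by realistic
artifact morphology.

## Preprocessing chain

Fixed order: zero-phase Butterworth band-pass 0.1–30 Hz of order 4
(forward–backward, i.e. effective order 8) plus a 60 Hz notch (Q 30) →
average-mastoid re-reference (mastoids then dropped) → baseline
correction (−100–0 ms) → rejection of epochs exceeding ±75 µV →
superblock concatenation → undersampling. Filtering prefers continuous
data; on epochs it relies on reflection padding and refuses segments
shorter than ~3× the filter length. Rejection operates on filtered,
baseline-corrected epochs; the provenance trail records trial counts at
every stage.

## Numerical choices and degenerate inputs

* AUC is the normalized rank-sum with ties counted ½; exact against an
  exhaustive pairwise oracle.
* Sample sd (ddof 1) everywhere; curve dispersion is the sd across the
  n_folds × n_repetitions AUC estimates (the only dispersion the
  procedure produces).
* liblinear is run with a fixed internal seed, tol 1e-4, max_iter 2000;
  all-zero feature columns yield constant decisions and hence AUC 0.5
  through the tie rule.
* Undersampling of an already-balanced set is the identity; a class with
  zero trials, all-rejected epoch sets, empty baseline windows, component
  support outside the epoch and overlapping searchlight windows raise
  explicit errors. Blocks too small for the per-block analysis are
  flagged "insufficient" rather than failing the session.

## Problem sizes used in the test suite

The two calibration benchmarks run at full scale (512 Hz, 400/200 trials,
5×10 cross-validation, full C grid). The simulation-heavy validity checks
use scaled-down sessions chosen to keep the suite quick while leaving the
tested contracts intact: 32–128 Hz sampling, 1–2 repetitions, single-value
C grids, and 24-permutation cluster tests (α = 0.05 remains attainable);
family-wise error is estimated over 100 null sessions, latency recovery
and wax/wane detection over 20 sessions each, amplitude–AUC coupling over
5 replicates of 17 subjects.

## Known limitations

* Independent noise across channels makes spatial pooling slightly more
  favorable than on real EEG.
* The searchlight's subject-level mode (averaged-ERP observations) is
  left to the caller: build per-subject ERP pseudo-trials upstream and
  pass them in as epochs.
* The paired montage comparison inherits max-statistic bias: removing
  pure-noise channels can slightly *raise* peak AUC, so "no significant
  difference" should be read one-sidedly (the reduced montage is not
  worse).
* No group-level (across-subject) inference; the cluster test is
  within-subject only.
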