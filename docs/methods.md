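# Methods

This note documents the models, estimators, parameter choices and known
limitations of `distractnet`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model of the synthetic generator

The generator emulates the statistical structure the analysis assumes in
real distracted-driving EEG: band-limited oscillatory activity in the four
canonical rhythms with state-dependent, band-specific cross-channel
coupling.  Per band *b*, channels in a *coupled group* receive

    x_ch(t) = κ_b · s_b(t) + (1 − κ_b) · e_ch,b(t),

a mixture of one shared narrowband Gaussian process per group and an
independent one per channel, both unit-RMS and synthesized exactly in the
frequency domain (complex Gaussian amplitudes on the in-band FFT bins).
This makes κ_b an interpretable coupling dial: the correlation between
group members is κ²/(κ² + (1−κ)²), zero at κ = 0 and one at κ = 1, and
phase locking and coherence increase monotonically with it.  Broadband
Gaussian noise (σ = 0.3 by default) is added on top.  Band amplitudes
default to δ 1.0, θ 1.0, α 1.2, β 0.8 — a coarse nod to the resting
spectrum's α prominence.

Linear mixing cannot produce *generalized* synchronization, which is what
the synchronization-likelihood estimator is specifically sensitive to.
States flagged `nonlinear` therefore superimpose a pair of
unidirectionally coupled Hénon maps (driver → response,
y_{t+1} = a − (C·x_t + (1−C)·y_t)·y_t + b·y_{t−1}, a = 1.4, b = 0.3)
on the first two channels of the first group, standardized and scaled to
RMS 0.6.

Default per-state coupling levels are **synthetic conventions**, not
measured values — no public distracted-driving EEG dataset with known
coupling levels exists to calibrate them against.  They encode the
qualitative signature the analysis targets: θ and β coupling elevated
under distraction, α slightly depressed, with θ dominating under visual
distraction (κ_θ 0.50 vs 0.15 normal) and β under cognitive distraction
(κ_β 0.45 vs 0.15), the cognitive state additionally carrying the Hénon
component (C = 0.8):

| state     | δ    | θ    | α    | β    | nonlinear |
|-----------|------|------|------|------|-----------|
| normal    | 0.20 | 0.15 | 0.35 | 0.15 | no        |
| cognitive | 0.20 | 0.25 | 0.30 | 0.45 | yes       |
| visual    | 0.25 | 0.50 | 0.30 | 0.25 | no        |

What the generator does **not** emulate: eye-blink/EMG artifacts, volume
conduction and realistic 10-10 spatial covariance, 1/f background spectra,
nonstationarity within epochs, or inter-subject variability (subjects
differ only through seeds).  Passing tests on this test bed therefore
demonstrate that the pipeline recovers planted coupling structure, not
that real EEG would be classified at the same accuracy.

Per-epoch seeds derive from `SeedSequence(master, spawn_key=(subject,
state, epoch))`, giving reproducible yet independent streams.

## Preprocessing

Resampling uses polyphase filtering (`scipy.signal.resample_poly`), which
anti-aliases on downsampling.  The 0.5–40 Hz noise filter is a 1537-tap
Hamming-window FIR applied forward–backward; the double pass gives > 56 dB
attenuation at 0.1 Hz and > 150 dB at 60 Hz while leaving mid-band
amplitudes within 5%.  Edge transients extend ~3 s per side, so the filter
is meant for continuous recordings before epoching, as in standard EEG
practice.  Epochs default to 10 s, matching the typical secondary-task display
duration in distracted-driving protocols, with per-channel mean
subtraction as baseline correction.

Band decomposition offers two methods:

- **wavelet** (default): wavelet-packet transform, db4, level 7 at
  512 Hz, giving 2-Hz terminal nodes; a band's signal is reconstructed
  from the nodes whose nominal support overlaps the band, a straddling
  node going to the band with the larger overlap and ties to the lower
  band.  Consequently the α/β edge at 13 Hz is approximated by assigning
  the 12–14 Hz node to α.  The wavelet family and level are this
  package's conventions (nothing in the analysis pins them down); both
  are config-exposed.
- **fir**: one zero-phase bandpass per band.  Since the taps are
  symmetric (linear phase), a single group-delay-compensated convolution
  is exactly zero-phase; this single-pass route is used here (and in the
  Monte-Carlo calibration loops) because forward–backward filtering costs
  an O(taps²) initial-condition solve per call.

Band edges are half-open [lo, hi) throughout, resolving the shared 4, 8
and 13 Hz boundaries.

## Synchronization likelihood

SL follows the canonical generalized-synchronization formulation: embed
each channel with dimension m = 10 and lag l = 10 samples; at each of
n_ref = 128 evenly spaced reference times choose a critical distance by
exact rank selection so that a fraction p_ref = 0.05 of the embedded
points in the admissible window (Theiler exclusion w₁ = 2·l·(m−1)
samples; outer window w₂ unbounded by default) are recurrences; SL_xy is
the fraction of x's recurrences that are simultaneously recurrences of y,
averaged over reference times.  Because both channels share the window
and the recurrence count k_i, the statistic is exactly symmetric, and its
compact time/window-averaged form is recovered as the mean over
reference times.

Numerical choices: squared Euclidean distances via the Gram identity in
float32 (ranking is scale-invariant; the rank selection itself is exact),
recurrence masks combined across all channel pairs by one BLAS matrix
product, per-row normalization by k_i folded in as √(1/k_i) weights.
Rank-selection ties can push a row's joint count marginally past k_i; the
final matrix is clipped to [0, 1].  n_ref = 128 was chosen as the point
where the independent-noise floor estimate is as stable as with the full
reference set (SD ≈ 0.0016 across seeds) at half the cost.

The estimator floor for independent signals is ≈ p_ref, so raw SL does
not span [0, 1] from zero; an optional rescaling (SL − p_ref)/(1 − p_ref)
is provided but off by default, since raw values are what connectivity
tables conventionally report (strengths ~0.08–0.13 for weakly coupled
EEG).  The pre-condition requires n_valid > w₁ + 20 samples; shorter
epochs are rejected with the required length in the message.

## PLV and coherence

PLV uses the analytic-signal phase of the already band-limited input with
no further filtering; all-zero channels (undefined phase) produce zeroed
entries and a log warning.  Coherence uses Welch-averaged modified
periodograms — Hann taper, 2-s segments, 50% overlap (0.5 Hz resolution
at 512 Hz) — averaged over in-band bins.  At least two averaging segments
are required (one segment gives MSC ≡ 1); independent signals carry the
known ~1/n_segments bias, which the tests verify rather than correct,
since the classifier consumes relative differences.

## Graph construction and topology

Thresholding keeps the round(s·n(n−1)/2) strongest off-diagonal weights;
ties break by lexicographic (row, col) after sorting by weight descending,
making graphs deterministic and nested across the sweep.  The diagonal is
fixed to zero so self-edges can never be selected.

Metrics on possibly disconnected graphs: L_g averages over reachable
pairs only (the unreachable fraction is logged); E_g counts disconnected
pairs as zero; C_g and E_l give nodes with fewer than two neighbors zero
contribution.  Shortest paths use breadth-first boolean matrix expansion,
O(diameter·n³) bit-ops, which beats sparse Dijkstra at the n ≤ 128 sizes
this pipeline sees; equivalence with brute-force Floyd–Warshall and
triangle enumeration is asserted to 1e−10 in the acceptance suite.

The degree admission rule mean-degree > 2 log(n) uses log base 10 by
default: a sweep starting at 13% sparsity gives a 63-node graph mean
degree ≈ 8.06 — below 2 ln 63 ≈ 8.29 but far above 2 log₁₀ 63 ≈ 3.60 —
so base 10 is the only reading under which the default grid itself is
admissible (the base is config-exposed).  The small-world scalar
σ = (C/C_rand)/(L/L_rand) uses 20 Maslov–Sneppen degree-preserving
rewired nulls (10 accepted swaps per edge, seeded); on saturated graphs
no swap is admissible, the nulls equal the graph, and σ = 1 exactly.
σ is evaluated per grid point when sweep validation is requested; because
it is the cost hotspot, feature extraction skips it by default and the
two admission rules are recorded as flags rather than used to drop grids.

The AUC aggregate is the trapezoidal integral over the sparsity grid
divided by the grid width, keeping the scalar unit-compatible with the
raw feature (a grid average).

## Recognition protocol

A protocol stated as 10-fold cross-validation with a reserved 10% test
share is ambiguous between nested evaluation and CV-as-test; both
readings are recorded: an outer stratified 90/10 split reserves a test
set, stratified 10-fold CV runs on the development split, and the report
carries both CV-mean and held-out metrics (tests and the acceptance
script use the CV mean).  Standardization is fitted inside each training
fold via a sklearn Pipeline, so no scaling leaks across folds — verified
by a permuted-label test whose CV accuracy collapses to chance.
Epoch-stratified splitting is the default; a subject-grouped mode (GroupShuffleSplit + StratifiedGroupKFold) avoids
identity leakage when subjects differ, which the current generator's
subjects do not.

Classifier defaults: "moderate" KNN read as k = 10 with Euclidean
distance; random forest with 200 trees; XGBoost with 200 rounds, depth 3,
learning rate 0.1, subsample 0.9; SVM with RBF (Gaussian) kernel and
probability estimates for ROC.  Multiclass ROC is one-vs-rest per class.
Feature importances (tree ensembles only) are normalized to sum to one
and aggregated into per-estimator and per-band shares.

## State contrasts and calibration

ANOVA is one-way across the three states on epoch-level values pooled
over subjects; a subject-mean mode selects the subject as the unit of
analysis instead.  The Bonferroni family defaults to the number of
feature columns tested in the run and is always declared explicitly in
the output.  Difference maps retain the ceil(k·n(n−1)/2) largest strictly
positive differences (k = 2% by default), with the same deterministic
tie-breaking as thresholding.

`power_check` calibrates the stage by simulation: each run regenerates a
compact cohort (2 subjects × 8 epochs/state × 8 channels × 4 s; 4-s
epochs give θ enough cycles for a stable PLV), computes per-epoch band
strengths via the FIR route for speed, and applies the corrected ANOVA.
Under the identical-state null the familywise rate calibrates type-I
error (Bonferroni bounds it at α); under the default effect cohort the
θ-band rejection rate measures power.

## Problem sizes in tests

The acceptance suite runs the full pipeline at 16 channels, 6 subjects ×
10 epochs/state × 3 master seeds (the full 63-channel montage is
supported throughout but scales SL and the sweep quadratically and is
exercised at single-matrix granularity); oracle comparisons use 200
random graphs of n ≤ 30; calibration uses 200 null and 50 effect
simulations.  These sizes were chosen so the whole suite completes in
minutes while keeping every Monte-Carlo tolerance comfortably above its
standard error.

## Known limitations

- Artifact removal (ICA/regression), bad-channel interpolation and
  re-referencing are upstream of this package; real recordings must be
  cleaned before ingestion.
- PLV is sensitive to volume conduction; no correction (e.g. imaginary
  coherence) is applied.
- Directed or lagged connectivity (Granger, PDC) is out of scope.
- Recognition accuracies reported for real driving cohorts rest on
  recordings that are not publicly available; nothing here claims to
  reproduce them.  The synthetic cohort's accuracies reflect its planted
  effect sizes.
- Compact printed forms of the SL statistic are often ambiguous about
  window constraints and sample counts; this package implements the
  canonical algorithm and treats such forms as its time/window average.
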