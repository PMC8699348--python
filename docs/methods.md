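# Methods

This note documents the models and estimators implemented in `eegmdd`, the
signal model of the synthetic cohort generator, the numerical choices that
are not visible from the API, and the fixed problem sizes used by the
stochastic test suite — together with what those tests do and do not show
about real clinical data.

## Preprocessing

A raw recording is a channels × samples matrix in microvolts with an
on-line reference (A2, the right mastoid, in the target protocol). The
analysis chain is:

1. **Re-reference** to the montage's reference electrode (Cz by default):
   every channel becomes `x_c − x_ref`, and the reference channel is removed
   from the data because its re-referenced trace is identically zero. This
   is how a 27-channel cap segment becomes the 26-electrode analysis
   montage.
2. **Band-pass** 2–50 Hz, Butterworth applied forward–backward
   (`sosfiltfilt`), so the filter is zero-phase and epoch-wise features are
   not skewed by group delay. The default order is 8 per band edge: the
   package's contract is that a 60 Hz mains tone retains < 5 % of its RMS
   after filtering, and a 4th-order design only reaches ≈ 16 % after the
   double pass. The order is a keyword argument for users who prefer a
   gentler filter.
3. **Optional cleaning hook**: `preprocess(..., cleaner=f)` applies an
   arbitrary `RawRecording → RawRecording` function between filtering and
   segmentation. Artifact removal (e.g., ICA-based ocular cleaning) is
   deliberately delegated to external tooling; this package does not
   reimplement it.
4. **Segmentation** into non-overlapping, contiguous 6 s epochs in temporal
   order. Trailing samples that do not fill a whole epoch are discarded —
   for the 90 s / 6 s protocol the division is exact (15 epochs of 3000
   samples at 500 Hz), so the truncation rule only matters for
   non-conforming inputs.

The default 26-electrode montage (FP1, FP2, F7, F3, Fz, F4, F8, FT7, FC3,
FCz, FC4, FT8, T3, C3, C4, T4, TP7, CP3, CPz, CP4, TP8, T5, P3, Pz, P4, T6)
is the extended 10–20 cap of a 32-channel system after excluding the three
occipital electrodes, with regions frontal (7 electrodes), central (5),
temporal (8) and parietal (6). The exact retained set and region memberships
are configurable through a two-column `electrode,region` text file; the
defaults are an explicit assumption, not a measured fact about any
particular cap.

## Features

All features are computed per epoch and averaged across epochs, so each
subject contributes exactly one value per feature. Band edges are treated
half-open, `[low, high)`, so the shared edges at 4, 8, 13 and 30 Hz are
never counted twice.

**Log band power.** One FFT periodogram per epoch (rectangular window),
band power by trapezoidal integration of the PSD over `[low, high)`, mean
over epochs, then log₁₀. The log base is a monotone rescaling and
irrelevant to any classifier downstream; base 10 makes gain effects easy to
read (a ×10 amplitude gain shifts every log band power by exactly 2). A
channel with zero power in any band is rejected with an error naming the
channel rather than propagating `-inf`.

**Band coherence.** Within each 6 s epoch, Welch auto-/cross-spectra with
1 s Hann windows and 50 % overlap (11 segments per epoch), magnitude-squared
coherence per frequency bin, mean over the bins in the band, then mean over
epochs. Averaging across Welch segments is essential: single-segment
spectra make the coherence ratio identically 1. The per-epoch-then-across-
epoch averaging is the default; `average="spectra"` instead pools the
cross-spectra over all epochs before forming the ratio, for users who
prefer the higher-dof estimator. With 11 segments the estimator's bias for
truly independent signals is ≈ 1/11 per bin, which is why the test suite
asserts a < 0.2 mean for independent noise rather than 0. The full
cross-spectral matrix is computed in one vectorized pass per epoch, so the
26-channel case (325 pairs × 5 bands) costs a few hundred milliseconds per
subject.

**Higuchi fractal dimension.** For time interval k and offset m ≤ k the
decimated subseries X(m), X(m+k), … has normalized curve length
L_m(k) = (Σᵢ |X(m+ik) − X(m+(i−1)k)|) · (N−1)/(⌊(N−m)/k⌋ k²); L(k) averages
over the k offsets, and the estimate is the ordinary-least-squares slope of
log L(k) against log(1/k) over the full integer grid k = 1…kmax (not
log-spaced). The estimate is ≈ 1 for deterministic signals and ≈ 2 for
white noise. Curve lengths are computed once up to max(kmax) per signal and
reused for the smaller kmax settings {50, 100, 150}. Constant signals are
rejected (zero curve length, log undefined).

**Katz fractal dimension.** KFD = log(L/A) / (log(D/L) + log(L/A)) with L
the total curve length of the sampled waveform, D its planar extent (the
maximum distance from the first sample) and A = L/(N−1) the mean step, so
that L/A = N−1. The waveform is embedded in the plane with the **time step
set to the signal's mean absolute increment** (equivalently: amplitude is
normalized to unit mean step before a unit-spacing embedding). The naive
unit-sample embedding makes KFD depend on the amplitude units of the
recording, which would contradict the package-wide contract that the
fractal-dimension features, like coherence, are invariant to per-channel
gain — the property that makes them attractive for multi-site data in the
first place. The dimensionless embedding preserves the two anchor
behaviours exactly (a straight ramp of any slope gives KFD = 1 because
D = L; unit-variance white noise stays within (1, 2]) while making the
estimate gain- and unit-invariant.

**Feature table.** The canonical column order is BP → COH → HFD → KFD; BP
band-major then electrode order, COH band-major then pair order by channel
indices (i < j), HFD kmax-major then electrode, KFD by electrode. With the
default montage the blocks are 130/1625/78/26 = 1859 columns with
boundaries at 130, 1755 and 1833. Descriptor strings
(`BP|beta|Pz`, `COH|alpha|F8-FT7`, `HFD|k50|C3`, `KFD|F7`) are the CSV
header, and the serialized table round-trips bit-exactly (pandas shortest
round-trip float formatting on write, `float_precision="round_trip"` on
read).

**CAR normalization.** `car_normalize_bp` subtracts, per subject and band,
the mean log band power over the electrodes of that band. It removes
subject-level baseline amplitude differences ("water level") while
preserving the within-band topography exactly; non-BP columns are
untouched.

## Classifiers

Labels are +1 (MDD) and −1 (HC); every decision function predicts MDD iff
its score is strictly positive.

**K-NN** (default K = 3) with the Euclidean metric. Distance ties at the
K-th neighbour are resolved by training-set order via a stable sort; a tied
vote (possible for even K) falls to the nearest neighbour's label. Both
rules exist purely for determinism.

**LDA.** w = Σ⁻¹(m_MDD − m_HC) with Σ the pooled within-class covariance;
the bias places the boundary through the midpoint of the class means under
equal priors and penalties, shifted by −ln(penalty_ratio · p_HC / p_MDD)
otherwise (penalty_ratio = C_MDD/C_HC, default 1; priors default to the
empirical class proportions). If the Cholesky factorization of Σ fails
(e.g., more features than samples) a ridge of 1e-6 · trace(Σ)/n is added;
passing `ridge=0` turns the fallback into an error instead.

**SVM.** The soft-margin dual is solved by libsvm (scikit-learn `SVC`,
stopping tolerance 1e-8) with the Gaussian kernel
K(a, b) = exp(−γ‖a − b‖²), for which K(x, x) = 1. Decision values are
recomputed in numpy from the stored support vectors, coefficients αᵢyᵢ and
bias, so a serialized model reproduces its decision function exactly after
a load, independent of scikit-learn internals. The solution satisfies the
KKT conditions (Σαᵢyᵢ = 0; free support vectors on the margin within 1e-4;
non-support vectors strictly outside it), which the test suite checks on
random problems.

**CK-SVM.** Two training steps at a single, shared (C, γ):

1. fit the base SVM;
2. collect the **support vectors within the margin** (SVWM) — support
   vectors with |decision| ≤ 1 — as the anchor set T; if T is empty, fall
   back to all support vectors with a warning. Each anchor's scale τᵢ is
   the mean of its ne = 5 smallest positive squared feature-space distances
   to the other anchors, with ‖φ(a) − φ(b)‖² = 2 − 2K(a, b); duplicate
   anchors (zero distances) are skipped, and with fewer than ne other
   anchors all available ones are used. The conformal factor
   c(x) = Σᵢ exp(−‖φ(x) − φ(xᵢ)‖²/τᵢ) defines the conformal kernel
   K̃(a, b) = c(a)c(b)K(a, b), whose Gram matrix is positive semi-definite
   by construction; the SVM is retrained on the same training set with K̃
   precomputed, and the bias is recomputed from the retrained dual's own
   KKT conditions.

At prediction time c(x) is evaluated for the test point from the stored
anchors and scales — the only reading that yields a usable decision
function. With c ≡ 1 the retraining reproduces the base SVM's decision
values to numerical tolerance; this identity limit is tested.

CK-SVM's accuracy advantage is data-dependent. In this package's synthetic
experiments the retraining tracks the base SVM closely at well-tuned
(C, γ) and improves it dramatically when the base kernel is under-resolved
(γ well below the inverse squared data scale, where the plain SVM
underfits): the conformal magnification restores resolution near the
boundary. On synthetic cohorts at grid-optimal hyperparameters it does not
systematically exceed the plain SVM; see "Desk-scale experiments" below.

## Model selection

**Cross-validation.** Stratified k-fold (default k = 5) with a seeded
shuffle; per-fold class counts differ from balance by at most one, the
held-out fold never influences training, and a fixed seed fixes the folds
and accuracies exactly. Reported as mean ± standard deviation (ddof = 1) of
per-fold accuracies in percent.

**Grid search.** The canonical grid is C ∈ {1000, 10000} ×
γ ∈ {0.0001, 0.0002, …, 0.0100}: 200 points, evaluated on identical folds.
Accuracy ties prefer the smallest γ, then the smallest C (weaker, smoother
models).

**Sequential backward selection.** From the full feature set, every
remaining feature is removed in turn, the reduced subset is scored by k-fold
CV, and the feature whose removal yields the highest accuracy is discarded;
ties discard the feature with the larger canonical column index. The trace
records the initial full-set evaluation plus one discard per size down to a
single feature; the optimal subset is the accuracy argmax over the whole
trace, with ties resolved toward the smaller subset (parsimony). With an
SVM wrapper and `reoptimize=True`, the grid search is rerun once per subset
size on the current subset and the winning pair is used for that size's
evaluations.

For the default LDA wrapper the inner loop uses per-fold sufficient
statistics: class means and the pooled covariance are computed once per
fold, the current subset's inverse covariance P is maintained by rank-one
Schur-complement downdating as features are removed, and every
single-removal candidate is scored in O(s) from P (the candidate weight
vector is `(P d − P[:, j](P d)ⱼ/Pⱼⱼ)` with row j dropped). P is rebuilt from
scratch every 48 removals to stop round-off accumulation, and if the
full-pool covariance is not positive definite the 1e-6·trace/d ridge is
applied once and kept for the whole trace. The fast path is exactly
equivalent to the generic per-candidate refit path on nonsingular data
(asserted in the tests) and makes the full 1859-feature backward sweep run
in minutes instead of days.

## Evaluation

Accuracy, sensitivity (true-positive rate on MDD) and specificity
(true-negative rate on HC) in percent; on a balanced test set accuracy
equals the mean of sensitivity and specificity exactly, and each
misclassified subject in a 120-subject test set costs 100/120 ≈ 0.83
percentage points. `evaluate_holdout` refuses to score any test subject
whose ID appears in the model's training set — subject-level leakage is the
classic way cross-validated EEG results fail to generalize, so the guard is
part of the API contract rather than a convention.

Frontal alpha asymmetry is (F4 − F3)/(F4 + F3) of **raw** (non-log)
epoch-averaged alpha powers, bounded in [−1, 1]; log powers can be negative
and break the range. Group comparisons use the two-sample Student's t-test
with pooled variance (two-sided), and effect sizes are Cohen's d with
pooled SD.

## Synthetic cohort generator

Per subject, for each band b (the five analysis bands):

    x_c = Σ_b amp_b · ( √ρ_cb · s_b + √(1 − ρ_cb) · e_cb )
          + 0.4 · n_c(1/f^β) + 0.15 · σ_site · w_c + mains tone,

then a per-channel site gain and a 20 µV overall scale. s_b is one shared
band-limited unit-variance source per band, e_cb are independent private
sources, and ρ_cb ∈ [0, 0.95] is the shared fraction. Because the band
component has unit variance regardless of ρ, the coherence of a pair (i, j)
in band b rises with ρᵢρⱼ while band powers stay fixed — a *pure*
connectivity effect. Band-power effects are expressed separately as dB
gains on amp_b. The per-band amplitudes (δ 1.0, θ 0.8, α 0.9, β 0.6, γ 0.4)
sketch a resting-state spectrum; the background is 1/f^β with β = 1.

Two subject-level traits create realistic between-subject structure: a
global synchronization trait (ρ jitter, SD 0.1, shared by every channel and
band) and, when effects are configured, a per-subject effect-expression
multiplier (truncated normal, mean 1, SD set by
`EffectConfig.expression_sd`) modelling clinical heterogeneity — some
affected subjects barely express the effect, which bounds the accuracy any
classifier can reach. At zero effects the two class generators are
identical in distribution by construction.

The recorded reference channel carries no shared band source. This is a
deliberate modelling choice: if it did, a mixing effect would change
cov(channel, reference) and therefore leak into band powers after
re-referencing, breaking the generator's "coherence-only effect" contract.

Site profiles apply lognormal per-channel gains (mean configurable, spread
0.05), a noise-floor scale and optional 60 Hz mains interference. A pure
gain change shifts every log band power by exactly 2·log₁₀(gain) and leaves
coherence and both fractal dimensions unchanged — the executable form of
the argument for amplitude-invariant features in multi-site data.

**What the generator does not emulate:** volume conduction and realistic
head geometry, ocular/muscle artifacts, non-stationarity within a
recording, electrode drift, and — importantly — the strong cross-feature
redundancy of real EEG (real band powers correlate heavily across channels;
the generator's private sources make its noise features closer to
independent). Passing tests on these cohorts therefore validates the
*estimators and the pipeline plumbing*, not clinical performance.

**Calibration of the effect mapping** (fixed seeds, asserted in tests): a
+0.3 shared-fraction boost on four electrodes in the alpha band separates
the targeted pairs' extracted alpha coherences by > 0.1 on average at 40
subjects per class, leaves band powers unchanged within sampling noise, and
class separation grows monotonically with the boost.

## Desk-scale experiments: fixed conditions and honest outcomes

The stochastic suite (`tests/test_acceptance.py`) runs at fixed desk-scale
conditions chosen once: a 6-electrode montage (F3, F4, C3, C4, P3, P4 +
Cz), 250 Hz, 24 s (4 epochs), two sites, 20 MDD + 20 HC per site
(40/class), 20 seeds; the coherence-only class effect is multi-band
(θ on F3·C3·P3, α on F3·F4·C3·C4, β on C4·P3·P4, shared-fraction delta
0.15, expression SD 0.6), mirroring the finding that connectivity effects
span bands and the whole scalp; SBS uses the LDA wrapper; CK-SVM and SVM
are compared at the fixed pair (C, γ) = (10⁴, 4·10⁻⁴). Zero-effect cohorts
(10 seeds) must stay in the 40–60 % CV band — they do (≈ 46 %).

Two further assertions in that suite are **known to fail** at these
conditions, and are left failing because the measured result is the honest
one:

- *Coherence share of the SBS optimum* (asserted ≥ 80 %, measured
  ≈ 0.63). The composition of a wrapper-selected subset is governed first
  by the feature pool: coherence is 87 % of the 1859-feature pool at 26
  electrodes but only 58 % of the 129-feature pool at 6 electrodes, and at
  these sample sizes greedy selection can drive the *selected* CV estimate
  to ~100 % even on pure-noise cohorts, after which the deterministic tie
  rule (discard the larger canonical index) systematically retains the
  low-index band-power block. Every class-informative feature the generator
  produces is a coherence feature — the recovery mechanism is real and is
  verified directly by the effect-calibration tests — but the *selected
  subset's composition* does not reach 80 % coherence at a desk-scale pool.
- *CK-SVM ≥ SVM mean CV at identical (C, γ)* (measured 79.5 % vs 83.3 %).
  The conformal retraining reproduces its base exactly in the c ≡ 1 limit
  and wins by double digits when the base kernel is under-resolved, but on
  these feature tables at the fixed pair it trails the plain SVM by a few
  points: the nearest-anchor scales give the conformal factor a dynamic
  range that acts as per-point kernel rescaling noise when feature-space
  distances do not concentrate. Published gains for the transform on real
  multi-site data are not derivable from synthetic cohorts of this kind.

## Numerical choices and degenerate inputs

- Filters: SOS realizations throughout; simulator band sources use
  4th-order Butterworth band-passes, the analysis band-pass defaults to
  order 8 (see above).
- Coherence of a zero-variance signal, log power of a silent channel, HFD
  and KFD of constant signals, single-class training sets, fold counts
  exceeding class counts, and train/test subject overlap all raise
  `ValueError` with the offending channel/subject named.
- Model serialization is JSON with full-precision floats; decision values
  round-trip to 1e-12 (exactly, in practice).
- Seeds: cohorts derive per-subject generators from a spawned
  `SeedSequence`, so a cohort is bit-reproducible from its spec and
  insensitive to the order in which subjects are generated.
- K-NN/grid/SBS tie rules are fixed as described so that every pipeline
  stage is deterministic under a fixed seed.

## Limitations

- EDF files can be read (via MNE) but not written; the package's native
  recording format is a TSV matrix with a JSON metadata sidecar.
- Artifact removal is a hook, not an implementation.
- The SBS fast path exists only for the default LDA wrapper; SVM-wrapped
  selection with per-size re-optimization is exact but slow at large
  feature counts.
- The simulator's realism limits are listed above; in particular,
  classifier rankings measured on synthetic cohorts should not be read as
  predictions about clinical data.
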