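# Methods

This note records the scientific and numerical choices behind `epicon`: what
each stage computes, which parameters matter, what the synthetic cohort does
and does not emulate, and where the design was genuinely open.

## Signal model of the synthetic cohort

Each subject's 19-channel recording is the sum of four parts, all in µV:

1. **MVAR carrier** (σ ≈ 14 µV): a stable order-8 multivariate
   autoregressive process.  The diagonal gives every channel a damped
   stochastic oscillator (poles at radius 0.45–0.65, centre frequency
   4–12 Hz, plus a weak lag-8 echo of 0.01).  Off-diagonal lag-1
   coefficients are sparse, positive, and restricted to electrode pairs
   within one of the four scalp groups — these are the *ground-truth
   directed couplings*.  The planted group (anterior-left by default) gets a
   denser, stronger base (density 0.6, weights 0.08–0.15) than the others
   (0.25, 0.03–0.07) so the class contrast acts on a clearly recoverable
   substrate.  Weights are rescaled (factor 0.85 per step) until the
   companion-matrix spectral radius of the base is ≤ 0.95 *and* the
   positive-class matrix at the reference effect size δ = 2 stays ≤ 0.98.
   Positive-class subjects have the planted-group couplings multiplied by
   `1 + effect_size`; an effect size that would destabilize the process is
   rejected with the offending spectral radius in the message.
2. **Band-limited oscillators**: per band (delta/theta/alpha/beta) one
   sinusoid per channel with random frequency inside the band and random
   phase, amplitudes 4.2/3.5/5.6/2.1 µV (±30% per channel), alpha dominant
   as in eyes-closed rest.  Random per-channel frequencies keep these
   components incoherent across channels, so they contribute realistic band
   power without spurious phase locking.
3. **1/f background** (σ = 4 µV): spectrally shaped Gaussian noise,
   power ∝ 1/f.
4. **Artifacts**: biphasic blink transients (≈ 0.6 s, < 4 Hz content, peak
   ≈ 150 µV) at a Poisson rate of 10/min, projected through a fixed frontal
   loading that decays exponentially with distance from a virtual
   peri-orbital source; and, with probability 0.05 per recording, one 3 s
   all-channel zero segment emulating a disconnection.

Metadata: diagnosis labels are Bernoulli at the requested prevalence, with
epileptic subjects split among focal-lesional / focal-non-lesional /
generalized-idiopathic in hospital-like proportions (≈ 75/17/8%); ages are
uniform on [16, 98]; sexes exactly balanced; the synthetic clinician's
"EEG result" is Bernoulli with sensitivity 0.660 and specificity 0.629 by
default, matching a realistic first-pass visual EEG reading.

**What this does not emulate:** volume conduction through a head model,
interictal spike morphology, sleep architecture, electrode impedance drift,
or any pathology-specific spectral signature.  A classifier succeeding here
shows that the *pipeline* recovers planted network structure through all of
its stages — not that the features would separate real patients.

The carrier-to-background balance matters: the MVAR carrier must dominate
(σ 14 vs ~7 µV combined background) for the planted coupling to survive
bipolar referencing.  The longitudinal bipolar montage is exactly
collinear in noise-free data (its 18 derivations span only rank 16, because
the lateral and parasagittal chains form loops), so the per-electrode noise
components are also what keeps the 18-channel MVAR fit well-posed — as they
do in real recordings.

## Preprocessing

* **Filter**: `firwin` Hamming band-pass, length `round(6.6·fs)` forced odd,
  edges 1 and 40 Hz; applied by centred FFT convolution, which for a
  symmetric FIR is exactly the delay-compensated (zero-phase-equivalent)
  output.  The windowed design leaves ≈ −64 dB of DC leakage; the taps are
  shifted by their mean to null DC exactly (pass-band perturbation < 1e−6).
* **ICA EOG removal**: FastICA with 15 components, fixed seed, fitted on a
  copy decimated to ≈ 64 Hz (EOG topographies are spatial and
  low-frequency; the decimation does not affect them) and applied at full
  rate.  Matching is on spatial loadings (mixing-matrix columns), absolute
  Pearson correlation, *strictly* above 0.8.  Only the matched components'
  contribution is subtracted, so when nothing matches the signal is returned
  bit-identical.  The default template is the generator's known frontal
  loading plus its left/right-antisymmetric counterpart; with real data one
  would derive it from a clean subject's ICA, as the template object allows.
* **Epoch cleaning**: per-channel peak-to-peak thresholds chosen from 40
  log-spaced candidates (10–500 µV) by 10-fold CV, minimizing the RMSE
  between the mean of sub-threshold training epochs and the median of
  validation epochs.  Among thresholds within 0.1% of the minimum error the
  largest is taken — on homogeneous clean data this selects a threshold
  above every epoch, so clean sets pass untouched.  Up to 3 supra-threshold
  channels per epoch are repaired by inverse-distance-weighted interpolation
  from the 3 nearest clean electrodes (standard 10-20 positions); epochs
  with more are dropped.  Cleaning runs on monopolar epochs, before bipolar
  derivation.
* **Decimation** is plain integer striding — content is already low-passed
  at 40 Hz, below the 64 Hz post-decimation Nyquist.

## Spectral and connectivity estimators

* **Welch**: 2 s Hamming segments, 50% overlap (0.5 Hz resolution inside 5 s
  epochs).  1/f correction multiplies each bin by its frequency; band masses
  are rectangle-rule sums over half-open bins `[lo, hi)` so the shared edges
  4/8/13 Hz are counted once.
* **GBP** uses the *population* variance of the four channel-averaged
  relative band powers, guarded by ε = 1e−12 so a perfectly even spectrum
  (variance 0) ranks above any finite-variance epoch.  Relative powers (not
  absolute) enter the variance, consistent with the goal of representing
  all bands evenly.
* **IMCOH/PLV**: multitaper cross-spectra (DPSS, time-bandwidth 4, 7 tapers)
  on the native 0.4 Hz grid of 2.5 s / 128 Hz epochs.  Coherency uses
  epoch-averaged spectra; PLV averages the unit-modulus cross-spectral phase
  over epochs first, takes the modulus per bin, then averages bins into the
  band.  IMCOH is stored as an absolute value; the sign (lead/lag) is
  deliberately discarded.  Connectivity band edges: delta 2–4 Hz and global
  2–30 Hz (a 2.5 s epoch cannot hold five cycles below 2 Hz); theta, alpha,
  beta unchanged.
* **MI**: Kraskov k-NN estimator (k = 3, Chebyshev balls), one value per
  epoch and pair, median over epochs (robust to outlier epochs), negative
  estimates clipped to 0.  Implemented as a numba kernel (brute-force
  distances beat trees at 320 samples); scikit-learn's estimator of the same
  quantity serves as an independent cross-check in the tests.
* **MVAR/PDC**: one order-8 model per subject over all selected epochs
  jointly; normal equations accumulate per epoch so no regression row spans
  an epoch boundary; ordinary least squares, no ridge.  PDC is evaluated on
  a 0.25 Hz grid from 0.25 to 30 Hz and normalized per source column
  (Σ_i PDC_ij(f)² = 1 identically); band values are bin means; the diagonal
  is zeroed before any graph use.

## Graph and asymmetry features

Node-level measures (strength; Onnela clustering on weights normalized by
the graph maximum, with directed matrices symmetrized; betweenness on
1/weight edge lengths, pair-normalized) are computed on the full 18-node
graph and then summarized (mean, population std) over each scalp group's
five members.  In/out-degree maxima and global efficiency are computed on
the 5-node group subgraphs.  Asymmetry ratios compare anterior-left vs
anterior-right and posterior-left vs posterior-right summaries as
max/min ≥ 1; when one side is zero (possible for betweenness or in/out
maxima on sparse matrices) the ratio is capped at 1e6 and logged — the cap
is a documented degenerate-input rule, not a measurement.

The canonical feature vector has 784 entries: 40 band power (median+std of
group-mean relative power per band, plus median+std of total absolute power
per group), 128 connectivity group summaries (IMCOH/PLV/PDC × 5 bands ×
4 groups × mean/std, MI global only), 468 graph (40 degree maxima, 108
strength with PDC mean-only, 128 clustering, 128 betweenness, 64
efficiency) and 148 asymmetry (96 strength/clustering/betweenness means,
20 degree maxima, 32 efficiency).  The taxonomy is enumerable with no data
(`epicon.netfeatures.feature_names`) and the assembly refuses vectors with
missing or unknown names.

## Classification protocol

Stratified 80/20 split; z-scoring with training μ and population σ
(constant features dropped); for the MLP an additional min-max map to [0,1]
with training extrema.  Reductions (ANOVA K-best, full-solver PCA with
default 17 components, deterministic correlation pruning at |r| > 0.92) are
fitted inside each CV fold via a sklearn pipeline, so no test or validation
information leaks into feature selection.  Correlation pruning iterates
features in canonical order and removes a feature only against
already-retained ones — deterministic by construction, unlike a random
victim choice, and therefore reproducible.  Hyperparameters maximize mean
5-fold stratified CV AUC.  The ROC cut-off maximizes Youden J = TPR − FPR
(ties resolved toward the lower threshold); the surrogate band is the 95th
percentile of the AUC over 100 seeded permutations of the test labels, and
"inside the band" means AUC ≤ that percentile.  Clinician fusion is
element-wise AND/OR on binary predictions; OR can only raise sensitivity
and AND can only raise specificity, which the tests verify exhaustively.

## Problem sizes in the test suite

The acceptance tests run the full pipeline at desk scale, chosen so the
whole suite completes on one CPU in well under half an hour: null
calibration uses 10 cohorts of 24 subjects (60 s recordings); planted-signal
recovery 3 cohorts of 60 subjects (60 s); the end-to-end smoke run 12
subjects at 120 s; the planted-PDC recovery invariant 3 × 60 subjects on the
direct simulation path (monopolar electrodes, where the coupling is
planted).  Single-feature class contrasts (e.g. within-group alpha PLV) are
checked at the generator's default 120 s duration, where estimation noise
is low enough for a 25-vs-25 subject comparison.  Decision thresholds
(AUC > 0.8, AUC ≥ 0.9, ≥ 90% surrogate coverage) are fixed properties of
the method, not tuned to the sizes.

## Known limitations

* The ICA stage uses FastICA; with few genuinely non-Gaussian sources the
  full decomposition often stops at the iteration cap without formal
  convergence.  The EOG component converges early and removal quality is
  unaffected (the tests require ≥ 50% frontal low-frequency variance drop
  and observe ≈ 96%), but the convergence flag is reported honestly.
* PDC computed on bipolar derivations dilutes directed structure (bipolar
  differencing mixes sources and the montage is near-collinear); on
  synthetic data the undirected estimators carry more of the planted
  contrast through the full pipeline, while PDC recovers it cleanly in
  monopolar space.  This mirrors a genuine limitation of sensor-space
  Granger measures under re-referencing.
* Epoch-selection shortfalls (< 50 epochs available) are logged and all
  epochs are used; short recordings therefore select every epoch and the
  ranking step is a no-op.
* The EDF writer emits plain continuous 16-bit EDF with 1 s records and
  symmetric physical ranges; sub-integer sampling rates and annotations are
  out of scope.
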