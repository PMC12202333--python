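# Methods

This note documents the models, estimator conventions and design choices
behind `eegfatigue`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## The detection problem

The unit of classification is a 1-s, two-channel (FP1/FP2) EEG epoch; the
target is a binary state label (normal = 0, fatigue = 1) assigned per
5-minute recording.  Because epochs from one subject are strongly
dependent, all validation is leave-one-subject-out (LOSO): a fold holds
out *every* epoch of one subject, and all fold-local transforms
(correlation pruning, z-scoring) and all model fitting happen inside the
fold on training rows only.  Epoch-level cross-validation would leak
subject identity into the training set and grossly overstate accuracy.

## Synthetic cohort model

Public forehead-EEG fatigue corpora are scarce, so the package generates
cohorts with the statistical structure the method assumes.  Per recording,
each channel is

    x(t) = b · [ Σ_bands osc_band(t) + σ_state · pink(t) ]

* **Oscillators.**  Four band-limited components (delta 1–4, theta 4–8,
  alpha 8–13, beta 13–30 Hz).  Each band's power is spread over three
  sinusoids at stratified random frequencies with random phases and slow
  (0.05–0.2 Hz, 30% depth) amplitude modulation — a band in real EEG is a
  broadband hump, not a line, and spreading the power keeps one extreme
  frequency draw from dominating the band's apparent speed.
* **Background.**  Unit-SD 1/f-amplitude ("pink") noise, scaled by a
  per-state amplitude σ_state.
* **Coupling.**  FP2 additionally receives `gain ×` a 1-sample-delayed
  copy of FP1's oscillatory component, so information flows FP1 → FP2 and
  symbolic transfer entropy into FP2 exceeds the reverse direction.  The
  1-sample lag matches the k = 1 symbol history of the transfer-entropy
  estimator, which makes the directed dependence detectable at 1-s epoch
  length.
* **Subject factor.**  A multiplicative baseline b = exp(0.1·z), drawn
  once per subject and applied to both states, so between-subject
  amplitude variance exceeds within-subject state variance — the feature
  of real cohorts that makes LOSO validation hard.

Fatigue multiplies, relative to normal (moderate preset): theta amplitude
× 1.8, delta × 1.4, beta × 0.6, background noise × 0.6, coupling gain × 2.
The direction of each term is standard drowsiness physiology — slow-wave
(theta/delta) enrichment, suppressed fast beta activity, and an overall
more regular signal, which is what lowers sample/fuzzy/spectral entropy in
fatigue.  "Weak" and "strong" presets scale these factors down/up, and the
"zero" preset makes the two state distributions identical (the null cohort
used to verify that the pipeline cannot manufacture accuracy without a
signal).  No public effect sizes exist for these quantities, so the
magnitudes are conventions chosen to make classification learnable but not
trivial at moderate effect; they are all exposed in
`SignalModelParams`.

What the generator deliberately does **not** model: eye blinks, electrode
drift and motion artifacts, event-related potentials, non-stationary
fatigue onset, or intermediate vigilance levels.  Passing tests on this
generator therefore demonstrate the pipeline's correctness and its
statistical behavior under the assumed signal structure — not performance
on real roadside recordings.

All randomness derives from `numpy.random.SeedSequence` keyed on
`(seed, subject_id, state)`, so cohorts are bit-reproducible and any
single recording can be regenerated in isolation.

## Preprocessing

Stage order: notch → band-pass → wavelet denoise → 1-s epoching →
variance gate → per-epoch min–max normalization.  The gate must see
physical units (μV²), hence it precedes normalization.

* Filters are 4th-order IIR (notch Q = 30 at 50 Hz; Butterworth band-pass
  1–50 Hz), applied forward–backward (`filtfilt`) for zero phase so epoch
  boundaries are not shifted.
* Wavelet denoising: db4, 4 levels, soft thresholding with the universal
  threshold σ·√(2 ln n).  σ is estimated from the **finest detail level**
  (its standard deviation).  After band-passing, that level contains only
  out-of-band residue and transient artifacts, so dense in-band
  oscillations do not inflate the threshold: a clean low-frequency tone
  passes with < 0.1% RMS error and alpha-band content is preserved
  (RMS ratio 0.99), while spiky artifacts, which spread energy across all
  levels, lose over half their peak amplitude.  A per-level MAD estimate
  was evaluated and rejected: it treats dense oscillations as noise and
  removed ~99% of alpha-band power, failing the basic fidelity requirement
  of a denoiser.
* The variance gate rejects an epoch if *any* channel's variance is
  ≥ 50 μV².  Normalization maps each channel of each surviving epoch to
  [0, 1]; the per-epoch scope guarantees no information crosses the
  train/test boundary.  A constant channel maps to 0.5 with a warning.

## Entropy estimators

Conventions, chosen once and frozen (the literature varies on most):

| Measure | Convention |
|---|---|
| AE | Pincus Φ(m) − Φ(m+1), self-matches included; m = 2, r = 0.7·SD, Chebyshev distance |
| SE | Richman–Moorman −ln(A/B), self-matches excluded, both template lengths counted over the first N − m templates |
| FE | templates mean-centered; membership exp(−(d/r)^n), n = 2 |
| K₂ | maximum-likelihood escape-time estimator at m = 6, delay 1; r₀ = mean |s − s̄|; pairs reaching the end of the series are censored; K₂ = −ln(1 − p̂) with p̂ = escapes / pair-steps |
| PE | coarse-grain by non-overlapping 2-sample means, order 5, delay 4; normalized by ln(5!) to [0, 1]; ties broken by temporal order |
| SPE | periodogram restricted to 1–50 Hz, Shannon entropy of normalized bins / ln(#bins) |
| STE | binarize increments (rise → 1), k = 1 histories, plug-in joint frequencies, bits |
| WLE | db3, 2 levels; Σ_j log c²_{i,j} per leaf, ordered [approximation, deepest detail, shallowest detail]; zero coefficients floored at 1e-12 |
| WPE | db3 full packet tree to depth 2; Shannon entropy (bits) of leaf-energy fractions |

Natural log is used for AE/SE/FE/K₂/PE/SPE/WLE and base-2 for STE/WPE, so
STE and WPE are in bits.  The named feature `STE_ch` is the information
flowing *into* channel ch from the other channel.  Per epoch this gives
22 features (7 scalars + 3 WLE components + 1 STE, per channel); the FFT
relative-band-power baseline adds 4 fractions (delta/theta/alpha/beta
share of 1–50 Hz periodogram power) per channel.

Estimator failures (zero in-band power, no template pairs within r₀,
too-short input) raise errors carrying the feature name — features are
never silently NaN.  A constant input returns 0 for AE/SE/FE/K₂ by
convention.  Every pairwise estimator is verified against a naive
double-loop oracle in the test suite (1e-10 for template estimators,
1e-12 for the symbolic ones).

## Feature pruning

Before each training fold, the Pearson matrix of the training rows is
scanned greedily in column order; a feature whose |r| with an
earlier-kept feature exceeds 0.98 is dropped, as is any zero-variance
feature.  Keep-first-in-order tie-breaking is deterministic;
anticorrelation also triggers removal.  The kept list from a fold's
training split is applied unchanged to its test split.

## Classifiers

* **LR** — L2 logistic regression, C = 1.0, on z-scored features.
* **ELM** — 200 sigmoid hidden units, input weights and biases
  ~ uniform(−1, 1) from a derived seed, output weights by ridge
  least-squares (λ = 1e-3); scores are the clipped linear read-out.
  Hyperparameters were chosen for stability at ~20 features.
* **LGBM** — 200 trees, depth ≤ 6, learning rate 0.1.
* **Stacking** — 5 stratified inner folds produce a 3-column out-of-fold
  probability matrix; a logistic meta-combiner is fitted on it; bases are
  refitted on the full training split for deployment.  `fusion="mean"`
  replaces the combiner with a plain average — both fusion readings are
  shipped because either is defensible for small base ensembles.  If the
  smaller class cannot fill 5 inner folds the fold count is reduced with a
  warning.

All randomness flows from one pipeline seed through named substreams
(ELM init, LGBM, inner folds, per-LOSO-fold model seeds), so every result
object is bit-reproducible.

## Metrics

Fatigue is the positive class.  Confusion matrices use a fixed 0.5
threshold; ACC/SN/SP/precision/recall/F1 are reported per held-out subject
and summarized as mean ± sample SD (ddof = 1); ratios with zero
denominators are reported as absent rather than 0.  ROC curves sweep all
score thresholds and AUC is trapezoidal (equal to the normalized
Mann–Whitney U, verified against an all-pairs oracle).  Pooled confusion
matrices (the sum over subjects) are reported alongside subject means; the
two generally differ under unbalanced folds, and both are informative.

## Scaled-down study sizes

The benchmark in `eegfatigue.study` runs 8 subjects × 60-s recordings at
200 Hz over five seeds (≈ 960 epochs per cohort), a size chosen so the
full pipeline — including the null-cohort leakage check and the
band-power baseline — completes in a few minutes on a single CPU while
keeping every structural property of a full-size study.  The full-size
epoch accounting (32 subjects × 2 × 300 s → 19,200 epochs) is exercised
separately by generation + epoching alone.

## Known limitations

* The synthetic generator's effect sizes are conventions, not calibrated
  to any measured cohort; absolute accuracies on it do not transfer to
  real EEG.
* ICA-based ocular artifact removal is deliberately omitted: with two
  channels the unmixing problem is ill-posed; the wavelet stage is the
  only transient-artifact suppressor.
* Entropy parameters are fixed at their defaults rather than re-optimized
  per dataset; a parameter sweep is a configuration loop left to the user.
* The EDF reader requires the optional `mne` dependency; EDF export is not
  implemented.
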