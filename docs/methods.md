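# Methods

## Problem and pipeline

Uterine electromyography (electrohysterography, EHG) recorded from abdominal
surface electrodes carries information about uterine activity that predicts
preterm delivery (birth before 37 weeks of gestation). The package implements
an analysis pipeline for 3-channel, 20 Hz, ~30-minute records in the TPEHG
(PhysioBank) layout:

1. **Band-pass to 0.3–3 Hz.** This band carries the uterine burst activity
   and excludes motion, respiration and maternal cardiac artifacts. Default:
   4th-order Butterworth applied forward and backward (zero-phase), matching
   the convention of the dataset's shipped filtered channels; records whose
   channels are already band-limited can skip the filter (`filter_spec=None`,
   `--no-filter`).
2. **Empirical mode decomposition (EMD).** Sifting decomposes the channel
   into intrinsic mode functions (IMFs) ordered from high to low frequency,
   plus a residue; the first ten IMFs are retained.
3. **Hilbert demodulation.** Each IMF's analytic signal gives its
   instantaneous amplitude a(t) = |z(t)| and instantaneous frequency
   ω(t) = dθ/dt (Hz).
4. **Entropy-ratio features.** The Shannon entropy of each amplitude and
   frequency track gives twenty entropy values per channel; features are the
   ratios E(i)/E(j) over all ordered pairs i ≠ j — 90 amplitude + 90
   frequency = 180 features per channel, 540 over three channels.
5. **SMOTE balancing and evaluation.** The minority (preterm) class is
   oversampled to parity; classifiers are scored by stratified 10-fold
   cross-validated ROC-AUC; feature screening uses per-feature Student
   t-tests; feature-set vs classifier effects on an AUC table are compared
   with a two-way main-effects ANOVA without replication.

## EMD details

* **Stopping rule.** The Rilling criterion with θ₁ = 0.05, θ₂ = 0.5,
  α = 0.05: sifting stops when |envelope mean| / envelope amplitude is below
  θ₁ on at least 95% of samples, below θ₂ everywhere, and the candidate
  satisfies the IMF extrema/zero-crossing condition. These are the
  conventional toolbox defaults; the sift budget is 100 iterations and
  non-convergence is reported, not raised.
* **Envelopes.** Natural cubic splines through the maxima and through the
  minima, after mirroring the two nearest extrema beyond each end. Mirroring
  suppresses end swings; with fewer than four knots the envelope degrades
  gracefully to linear interpolation.
* **Plateaus.** A flat run that is a local extremum contributes a single
  knot at its midpoint, avoiding duplicate spline abscissae.
* **Termination.** Decomposition stops when the residue has fewer than three
  interior extrema (monotone residue) or at `max_imfs` = 14 — the paper-scale
  records decompose into 11–13 IMFs, so 14 leaves headroom without wasted
  sifting. Completeness (ΣIMF + residue = input) is exact by construction:
  residues are formed by direct subtraction, so reconstruction error is at
  rounding level (measured ~1e-16 relative RMS).
* **Records with fewer than ten IMFs** are excluded from feature matrices,
  with a structured skip report, rather than zero-padded: padding would
  fabricate entropy values for modes that do not exist.

## Hilbert details

* Phase uses the four-quadrant angle (then unwrapped), not a two-quadrant
  arctan, which is ambiguous by quadrant.
* Frequency uses central differences (one-sided at the ends), keeping output
  length equal to input length. Negative instantaneous frequencies are
  retained: the entropy estimator operates on the empirical distribution and
  clipping would distort it.
* Each component carries a `valid_range` trimming 5% of samples at each end;
  all downstream entropy estimation and all tone/chirp accuracy guarantees
  apply to that interior range, where the FFT-based Hilbert transform is free
  of boundary transients.

## Entropy estimation

Equal-width histogram with 100 bins over [min, max] of each track (bin count
and log base are configuration knobs). Because the features are ratios, the
log base cancels exactly; the suite verifies feature invariance between
natural-log and base-2 entropies to 1e-12 relative.

Numerical guards:

* A track whose total spread is ≤ 1e-9 of its magnitude is treated as
  constant (entropy 0). Equal-width binning over [min, max] is scale-free,
  so without this guard floating-point ripple on an exactly constant
  amplitude track (e.g. a pure tone's analytic modulus) would read as
  high entropy.
* A zero-entropy denominator makes a ratio undefined; such features are set
  to the sentinel 1e6 and the vector flagged, so degenerate tracks are
  visible rather than silently poisonous.

## SMOTE

Each synthetic minority row is x + u·(nn − x) with u ~ U[0,1] and nn one of
x's k = 5 nearest minority neighbours (Euclidean distance on raw feature
values, as in canonical SMOTE; a `standardize` flag is available). Synthetic
counts are spread as evenly as possible across minority rows (floor/ceil of
the mean count), so non-integer oversampling rates — 38 → 262 is ×6.9 — hit
the target exactly. All randomness flows from a single seed.

Two cross-validation protocols are exposed because SMOTE placement matters:

* `paper`: balance the full cohort, then split — reproduces the historical
  protocol, but interpolated copies of test records can appear in training
  folds, inflating AUC.
* `fold-safe` (default): split original records first, balance each training
  fold only; no synthetic row ever reaches a test fold (asserted from origin
  flags in the suite).

## Classifiers

Pluggable adapters over scikit-learn with fixed seeds: polynomial-kernel SVM
(degree 1), 100-tree random forest, one-hidden-layer (20-unit) perceptron,
50-round AdaBoost on depth-1 trees, Gaussian naive Bayes as the
Bayesian-network stand-in, and L2 logistic regression for simple logistic.
Scale-sensitive learners (SVM, MLP, logistic) are z-scored on the training
fold. The pipeline's discriminative claim is about the features; classifier
internals are deliberately standard.

## ANOVA

For a complete classifiers × feature-sets AUC table (6 × 2): SS_method =
r·Σ(colmean − grand)², SS_classifier = c·Σ(rowmean − grand)², SS_error by
subtraction; df = (c−1), (r−1), (r−1)(c−1); F = MS_factor / MS_error with
p from the exact F distribution. The decomposition is exact (verified against
a brute-force total-variance oracle and against a statsmodels OLS fit). A
zero-error table (duplicated columns) returns F = 0 for an exactly null
factor rather than 0/0.

## Synthetic data generator

The generator emulates the statistical shape of band-limited EHG, not its
physiology: per channel, pink (1/f) noise band-passed to 0.3–3 Hz (RMS 0.35)
plus a small wide-band floor (6% of noise RMS), and 6–12 Hann-windowed
~1-minute amplitude-modulated sinusoidal bursts (contraction surrogates,
unit amplitude). Defaults reproduce the study layout: 20 Hz, 1800 s
(36,000 samples), 3 channels; a (262, 38) cohort mirrors the clinical class
imbalance. The broadband floor guarantees a deep IMF ladder: 30-minute
records decompose into ≥ 10 IMFs (typically 12–13), matching the 11–12
reported for real records.

The class effect shifts the preterm burst-carrier band upward (term
0.4–1.0 Hz; "strong" preterm 1.5–2.6 Hz; "weak" intermediate) and deepens /
complicates the amplitude modulation (term depth 0.25; strong 0.85 with a
second modulator), so it propagates into both the frequency- and
amplitude-entropy halves of the feature vector. `class_effect="none"` makes
the label distributions identical — the negative control.

What passing tests on this generator do **not** show: performance on real
EHG (electrode artifacts, inter-subject variability, gestation-dependent
drift, non-sinusoidal contraction morphology are all absent). The published
headline AUCs are bound to the clinical dataset and to unreported
entropy/SMOTE/classifier settings; the suite therefore checks the method's
verifiable properties (exact reconstruction, closed-form demodulation,
count structure, protocol hygiene, sensitivity/null behaviour) rather than
those numbers.

## Problem sizes used in the suite

End-to-end checks use (50, 50) cohorts at the full 30-minute record layout
(~70 s of EMD per cohort); unit tests use 64–36,000-sample signals chosen to
exercise each property at the smallest scale that demonstrates it. The
acceptance script extracts features from one full-scale record and balances
a 300-row cohort.

## Known limitations

* Only WFDB format 16 with a single signal file per record is supported.
* No ensemble/multivariate EMD; no Hilbert spectrum imagery.
* The non-EMD comparison feature set (RMS, median/peak frequency, sample
  entropy) is not recomputed; an externally supplied AUC table feeds the
  ANOVA comparison.
* The Bayesian-network classifier is a naive-Bayes stand-in; exact historical
  classifier internals (WEKA) are out of scope.
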