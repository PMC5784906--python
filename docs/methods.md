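# Methods

`rarelulc` studies a recurring problem in agro-ecological remote sensing:
land-cover classes of policy interest (here, annual dryland and perennial
crops in a small monsoon-climate catchment) are *rare*, and standard
classifiers trained on the raw class distribution learn the dominant
forest class at their expense.  The package implements the full analysis
chain — QA filtering of multi-band 16-day composite reflectance series,
training-set resampling (Tomek-link cleaning, LN-SMOTE oversampling,
random undersampling), repeated stratified cross-validation of a random
forest under four scenarios, and the diagnostics that explain the
outcome — together with a synthetic scene generator that stands in for
the satellite and census data.

## The synthetic scene generator

The generator emulates the statistical structure the analysis depends
on, not radiometric physics:

* **Class distribution.** Default pixel proportions follow the reference
  ground census of the modeled catchment (six classes, 691/179/135/82/35/22
  pixels out of 1144; the majority class covers ~60% of pixels).  Counts
  are apportioned by largest remainder and enforced exactly by a repair
  pass, so realized label counts match the requested proportions.
* **Phenology.** Each class has a per-band double-logistic endmember
  curve: baseline reflectance plus a green-up/senescence pulse.  Forests
  green up earlier (half-amplitude day ~120–125) and faster than crops
  (150–175), the near-infrared band B2 carries the largest seasonal
  amplitude, and the three agricultural minority classes (annual
  dryland, fallow, perennial) are deliberately close to one another
  while paddy rice is set apart by its flooded low-infrared baseline and
  mixed forest sits near deciduous forest.  Per-pixel realizations
  jitter the parameters (baseline sd 0.008, relative amplitude sd 0.12,
  midpoints sd 7 d, relative rates sd 0.15) and add observation noise
  (sd 0.008); `jitter_scale` turns the intra-class variability off for
  exact endmember checks.
* **Mixed pixels.** A pixel of class *c* is pure (one-hot fraction) with
  a per-class probability (defaults: forests 0.95/0.85, paddy 0.85,
  annual 0.55, fallow/perennial 0.45 — the cropland classes are
  inherently mixed, the forests and paddy largely pure).  Mixed pixels
  draw Dirichlet fractions over the pixel's class and two spatially
  neighboring classes, conditioned on the main share staying in
  (second-largest, 0.5], so the share of pixels whose main fraction
  exceeds 0.5 tracks the configured purity and the assigned label always
  equals the argmax fraction.  Spectra of mixed pixels are linear,
  fraction-weighted combinations of endmember realizations — the same
  reading of interpolation-based oversampling as a linear spectral
  mixing operation that motivates applying SMOTE-type methods to
  reflectance series in the first place.
* **Spatial layout.** A forest ring surrounds an interior mosaic of
  randomly split rectangular fields, making patch density meaningful.
* **Clouds.** Each composite is contaminated independently with
  probability `cloud_prob` (default 0.165): additive half-normal spikes
  in bands 1, 3 and 7 (scales 0.12/0.15/0.08 plus a 0.02 floor; band 2
  untouched), "VI quality" set to 3 and "VI usefulness" raised to ≥ 5.
  The default was calibrated once so the expected share of pixels
  failing the two exclusion rules (≥3 consecutive cloudy composites, or
  ≥4 cloudy summer composites) matches the ~7% the study protocol
  reports for the real tile; at 40×30 pixels the filter typically keeps
  ~1110–1125 of 1200.

What the generator does **not** emulate: topography and directional
effects, genuinely autocorrelated cloud fields, sensor noise structure,
sub-pixel geolocation error, and the eight census classes too rare to
classify.  Passing tests therefore demonstrate the pipeline's
correctness and the qualitative resampling effects under controlled
imbalance and overlap — not performance on any real tile.

## QA filtering

Composite dates are the 23 nominal 16-day start days of one year; the
first four (winter snow/ice) and the last are dropped, leaving 18.
Summer is the day-of-year interval [129, 241].  The four steps:

1. **Despiking** (bands 1, 3, 7): summer values strictly above the 75%
   linear-interpolation quantile of the summer subseries become missing.
   B2 is exempt.  Missing values are excluded from the quantile and
   despiking is applied once, not iterated.
2. **Gap closing**: locally weighted quadratic regression (loess,
   span 0.5, tricube kernel, no robustness iterations) with prior
   weights from the "VI usefulness" flags (default map 0–1→1.0, 2→0.8,
   3→0.6, 4→0.4, ≥5→0.1; configurable).  Only gaps are filled; observed
   values are untouched.  A band with fewer than 4 valid points marks
   the pixel unusable.
3. **Median filtering**: running median of width 5 (windows shrink at
   the series ends), replacing only low-quality composites
   (VI quality = 3 or VI usefulness ≥ 5).
4. **Smoothing/resampling**: a final weighted loess evaluated at 18
   evenly spaced dates between the first and last retained acquisition
   date, flattened band-major into a length-72 feature vector.

The loess is implemented directly (local weighted least squares with
tricube × prior weights; rank-deficient local systems widen their
window) because no installed smoother offers degree-2 local fits with
prior weights; it is pinned against an explicit normal-equations oracle.

## Resampling

Tomek links are mutual-nearest-neighbor pairs with different labels;
only the majority-class member is removed.  LN-SMOTE uses k = 5
all-class neighborhoods with safe levels and the five safe-level-ratio
cases described in the module docstring; across-class draws scale the
interpolation weight by sl(Q_n)/k.  Implementation choices the
published description leaves open:

* neighborhoods are frozen on the original (post-Tomek) training rows;
  synthetic rows never serve as neighbors;
* seed points cycle through the minority members in random order;
* noise skips are bounded by a draw budget of 10× the requested count,
  so a fully noisy class terminates with zero generated rows;
* the duplicate case emits an exact copy flagged `duplicated`.

Scenario S3 oversamples the three smallest classes up to the
second-largest class count of the training fold (the study's "number of
annual dryland training pixels" generalized so the target adapts to any
fold size); S4 additionally undersamples the majority class to the same
target.  Test folds are never resampled.

## Experiment protocol

Repeated stratified 6-fold cross-validation; each class is split
separately, so per-class fold sizes differ by at most one, and the same
fold plan is shared by all scenarios within a repetition.  The
classifier is a random forest with unpruned trees (nodesize 1);
`mtry` is tuned per outer fold by an inner stratified 5-fold grid
search on the macro F-score, ties going to the smallest value.  Tuning
runs on the scenario-transformed training set with plain inner folds
(re-resampling inside every inner fold would multiply runtime ~15×; the
transformed-set reading matches the stated protocol).  Seeds derive
hierarchically (master → repetition → scenario → fold), so any fold is
reproducible in isolation.

The *full* profile is the study protocol: 1000 trees, 10 repetitions,
mtry grid 2..72.  The default *reduced* profile (200 trees,
3 repetitions, grid {2, 8, 32}) keeps a complete four-scenario run on a
~600-pixel scene within minutes on one CPU while preserving the
protocol's structure; all reported qualitative effects already appear at
this scale.

## Diagnostics

* **Separability**: per-band 18-dimensional Gaussian summaries (the full
  72-dim covariance is singular for small classes), Bhattacharyya
  distance and JMD = 2(1 − e^(−B)).  When a covariance is rank-deficient
  or the average is ill-conditioned, the quadratic term uses the
  Moore–Penrose pseudo-inverse and the log-determinant term floors all
  eigenvalues at a common tolerance (1e−10 × the largest eigenvalue of
  the average covariance), with a final clamp at B ≥ 0.  Flooring rather
  than dropping the near-null eigenvalues keeps the determinant term
  dimension-consistent; the price is that a rank-deficient class reads
  as near-perfectly separable (JMD ≈ 2) from a full-rank one, so such
  pairs are flagged `pseudo_inverse` and should be interpreted with
  caution.
* **Mutual information**: the k-nearest-neighbor (KSG) estimator in its
  discrete–continuous form (within-label k-th neighbor distances define
  per-point radii; digamma averages combine the counts), k = 3 by
  default, computed per (band, date) scalar feature on the cleaned
  reflectances as-is.  The estimate can be slightly negative under
  independence; the normalization MI* = sign · √(1 − e^(−2|MI|))
  preserves that sign.  The estimator is cross-checked against an
  independent numerical-quadrature oracle and against scikit-learn's
  clipped implementation.
* **Entropy** of the class distribution is reported in bits, so six
  balanced classes give log₂6 ≈ 2.58.
* **Landscape**: patch density counts connected same-class components
  (8-neighbor connectivity by default, configurable) per 100 ha at
  6.25 ha per pixel; purity is the share of a class's pixels whose
  main-class fraction strictly exceeds 0.5.

## Numerical conventions and degenerate inputs

Quantiles use linear interpolation with strict ">" comparisons; k-NN
ties break to the lower index; majority-label ties break to the lowest
class id; per-class rates that are undefined in a fold (empty class)
propagate as missing and are excluded from macro averages with a
warning; G-mean is zero as soon as one class is never recovered; the
uniform draw with a = b degenerates to the constant a.

## Known limitations

The pseudo-inverse JMD saturates near 2 for rank-deficient classes
(see above).  The oversampling target uses the training fold's
second-largest class count rather than a hard-coded pixel number, so
absolute class sizes differ slightly from the original protocol on
small scenes.  Mutual-information profiles on scenes below ~200 pixels
are noisy (a few hundredths of a nat under independence).  The scene
raster I/O writes plain multi-page TIFF without geographic referencing.
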