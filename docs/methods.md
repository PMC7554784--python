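# Methods

`sersclass` implements a peak-based chemometric pipeline for two-class
discrimination of surface-enhanced Raman spectra (SERS) of cancer cells:
tumor repopulating cells (TRCs) versus parental control cells. Because no
public spectra exist for this assay, the package ships a synthetic-spectrum
generator whose defaults encode the study conditions the pipeline is built
for (51 spectra: 37 control from 8 biological samples, 14 TRC from 5
samples, on a 1.1 cm⁻¹ grid over 350–1800 cm⁻¹); every downstream stage is
exercised and tested against spectra with known planted markers.

## Synthetic spectrum model

Each spectrum is

```
I(ν) = s · [ Σ_b A_b · e · L(ν; c_b + δ_b, w_b) + B(ν) ] + ε(ν)
```

* `L(ν; c, w) = (w/2)² / ((ν − c)² + (w/2)²)` — unit-height Lorentzian with
  FWHM `w` (the standard Raman line shape); Raman band amplitudes `A_b` are
  class-independent for shared bands and class-specific for differential
  bands.
* Default shared bands sit on well-known cellular wavenumbers (728, 855,
  1002, 1092, 1449 cm⁻¹, …) with amplitudes of order 1; the five default
  differential bands (1201.5, 1267.6, 1420.5, 1610.4, 1654.9 cm⁻¹) lie in
  the Amide III–Amide I region with TRC:control amplitude ratios of ≈2–2.4×
  in either direction. Their centers are the ground truth the generator
  returns.
* `δ_b ~ N(0, shift_jitter²)`, default 1.0 cm⁻¹ — peak-position jitter of
  roughly one grid step, emulating instrument and matrix shifts.
* `e = exp(N(0, sample_effect_sd²))`, default 0.10 — one multiplicative
  amplitude effect shared by all spectra from the same biological sample,
  inducing the within-sample correlation real data shows.
* `s = exp(N(0, intensity_jitter²))`, default 0.15 — per-spectrum scale,
  modelling the irreproducible absolute SERS enhancement that motivates
  max-peak normalization.
* `B(ν)` — per-spectrum cubic polynomial (scale 0.5) plus a broad Gaussian
  autofluorescence hump (center U(700, 1500) cm⁻¹, width U(300, 600) cm⁻¹,
  amplitude ≈2× the band scale).
* `ε ~ N(0, noise_sd²)`, default 0.02 (≈2 % of a unit band).

Randomness fans out from a single root seed (one stream per spectrum plus
one for the sample effects), so a config is bit-reproducible. The generator
does **not** model cosmic-ray spikes, detector etaloning, wavenumber-
dependent noise, or physical SERS enhancement; a pipeline that passes on
these spectra is validated for its statistical logic, not for robustness to
those artifacts.

## Preprocessing

Baseline removal is a sectional iterative-clipping polynomial fit
(modified-polyfit family): within each section a degree-3 polynomial is
least-squares fitted, data above the curve are clipped down to it, and the
fit repeats until the largest change falls below `clip_tol` × the spectrum
range (default 1e-6) or `max_iter` (100). Sections default to one per
500 cm⁻¹; adjacent section fits are averaged over a ±2-point window at each
cut so the corrected spectrum is continuous. Normalization divides each
spectrum by its own maximum (there is no single band stable enough in SERS
data to normalize to).

**Convergence floor.** The clipping iteration has no exact fixed point: a
least-squares fit whose residuals are all one-sided must interpolate, which
a finite-order polynomial cannot do. In practice the converged curve
overshoots the spectrum by up to ~0.1 % of the intensity range, and a second
correction pass moves a spectrum by up to ~1 % of its range (measured on a
polynomial + Lorentzian phantom; stable from 10³ to 2×10⁴ iterations). The
property tests therefore check the sub-percent floor, not the per-iteration
tolerance: baseline correction is idempotent and one-sided only up to this
floor, which is far smaller than any band of interest but many orders of
magnitude larger than `clip_tol`.

## Peak representation

A point is a peak if it strictly exceeds both neighbours; a plateau strictly
above its flanks reports its leftmost point; endpoints are never peaks.
Peaks with prominence below `min_prominence` × range are dropped
(`scipy.signal.peak_prominences`); the default 0 keeps every bare local
maximum. The peak matrix's columns are the union of all spectra's peak
wavenumbers, with zeros where a spectrum has no peak — matched exactly on
the shared grid. An optional `merge_tol` (cm⁻¹) collapses neighbouring
columns but defaults off, since tolerance binning changes the statistics in
ways that deserve a deliberate choice. Note that with per-spectrum position
jitter, exact matching dilutes each column (the same physical band spreads
over 2–3 columns); a small prominence floor (≈0.02) is then important to
keep noise maxima from flooding the union.

## Feature scoring

All scores are univariate (per wavenumber); standard deviations use the
sample (n−1) divisor throughout.

* t-statistic: `|µ₀ − µ₁| / √(σ₁²/n₁ + σ₀²/n₀)` (unequal-variance form).
* Signal-to-noise ratio `w` (Golub-style): `|µ₀ − µ₁| / (σ₀ + σ₁)`.
* RELIEF, per-feature variant: for each sample, the hit (miss) is the
  nearest other same-class (opposite-class) value *in that feature alone*;
  the weight is the mean of `|x − miss| − |x − hit|`. Averaging over
  samples versus summing changes scores by a constant factor only, never
  the ranking. Unlike t and w, RELIEF is not invariant under feature
  rescaling (scores scale with the feature), which is documented and
  tested.
* Degenerate denominators: zero with equal class means scores 0; zero with
  unequal means (a perfectly separated constant-within-class feature) is
  flagged and placed above every finite score.
* Ranking sorts by descending score with ties broken by ascending
  wavenumber.

PCA standardizes every feature (constant features get unit scale) and
eigen-decomposes the covariance of the z-scored data, computed via thin SVD
(cheap when features ≫ samples, identical on the nonzero spectrum). The
largest-magnitude loading of each component is made positive so signs are
reproducible. Score-then-PCA chains select the top-k features first and fit
the PCA on the selected submatrix, recording the selected wavenumbers so
marker reports can name them.

## Cross-validation

Folds are class-constrained: the minority class is shuffled and dealt one
spectrum per fold (capping the fold count at the minority size — 14 here),
the majority class is shuffled and dealt round-robin, so every test fold
holds exactly one TRC and two or three controls. Fold accuracies aggregate
with the population (divide-by-k) standard deviation — with 13 folds at 1.0
and one at 0.75 this gives 0.982 ± 0.064 (the sample formula would give
0.067).

Classifiers: a hand-rolled kNN (Euclidean; distance ties prefer the lower
training index; an even-k vote tie goes to the nearest neighbour's class —
these tie rules are part of the contract, which is why scikit-learn's kNN
is not used) and a soft-margin SVM delegated to `sklearn.svm.SVC`
(C=1, polynomial degree 3, `gamma="scale"`; linear/poly/sigmoid/rbf).

Two protocols: the default `safe` mode fits selection and PCA inside the
training folds only; `paper_mode` fits them once on the full dataset before
splitting, as small-sample spectroscopy studies commonly do. The mode is
recorded in every result row. On strongly separated synthetic data both
modes succeed; on weak effects paper-mode accuracies are optimistic, which
is precisely why both are provided.

The grid runner crosses data type (raw / baseline-corrected / peak matrix)
× normalization × reduction (t, w, RELIEF, PCA, score+PCA chains) ×
dimension count × classifier, one constrained CV per cell, sorted by CV
accuracy, with an overfit flag wherever training accuracy exceeds test
accuracy.

## Marker reporting

Selected wavenumbers are matched (within a tolerance defaulting to 2 cm⁻¹,
about two grid steps) against a bundled band-assignment table covering
1116–1665 cm⁻¹ (Amide I/III, tyrosine, collagen and nucleobase bands, one
row per assignment; multiple assignments per band are all preserved). The
clustering summary reports the fraction of the selection inside a band of
interest plus the maximal runs of consecutive selected peaks inside it. A
match is a literature pointer, not a causal claim.

## Problem sizes and numerical choices

The default grid (252 configurations × 14 folds on 51 spectra) runs in
about 10 s in paper mode and about 45 s in safe mode; the marker-recovery
property uses 10 generator seeds; the label-shuffle null uses 20
permutations. These sizes give stable means (shuffle-mean standard error
≈0.01) while keeping the full suite fast. Tolerances: scorer brute-force
agreement is checked to 1e-10 (pure floating-point identity of two
evaluation orders); planted-marker recovery counts a marker as found when a
selected wavenumber lies within 3 cm⁻¹ (position jitter plus two grid
steps) and is run at `noise_sd=0.005` with a 0.02 prominence floor, the
low-noise regime in which peak-matrix columns are band-dominated.

## Known limitations

* The per-feature RELIEF follows the univariate description it implements;
  the original multivariate RELIEF (neighbours in the full feature space)
  would weight correlated bands differently.
* Exact peak matching fragments jittered bands across neighbouring columns;
  `merge_tol` exists but the interaction of binning width with the scorers
  is deliberately left to the user.
* The per-sample amplitude effect makes shared bands carry chance class
  signal (only 13 samples); with strong effects this does not disturb
  classification but can pull shared bands into the top of a ranking.
* Baseline correction is validated on polynomial-plus-peak phantoms; real
  autofluorescence with sharp steps (detector seams) would need section
  bounds placed at the steps.
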