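# Methods

This note records the statistical procedures the package implements, the
defaults it chooses where the methodology leaves them open, what the
synthetic scenes do and do not emulate, and the numerical conventions that
matter for reproducing its outputs.

## Band-information ranking (ABS)

Bands are placed in a fixed analysis order — purple first, yellow last, so
the six substantive bands (B, G, R, NIR, RE1, RE2) are interior — and each
interior band is scored

    I_i = sigma_i / ((|r_{i-1,i}| + |r_{i,i+1}|) / 2),

the reflectance standard deviation over the mean absolute Pearson
correlation with the two adjacent bands. The index is sometimes written with
the correlation term beside sigma rather than under it; this package divides,
because the method's stated selection principles require higher adjacent
correlation (redundancy) to *lower* a band's score, and because division
makes the index scale linearly with sigma (a property the tests assert).
Endpoint bands have only one neighbor: they are assigned index 0 and share
the bottom rank rather than competing on a one-sided correlation. When both
neighbor correlations vanish the divisor is guarded by epsilon = 1e-6 and
the band is flagged.

## Class separability (JM, J_Bh)

Each class is summarized by a Gaussian signature (mean, unbiased covariance,
pixel count) over the band subset of the scheme under study — signatures are
recomputed per scheme, not once on the raw bands. Pairwise separability is
the Jeffries–Matusita distance JM = 2(1 - exp(-B)) with the Gaussian
Bhattacharyya distance

    B = (1/8) d' S^-1 d + (1/2) ln( |S| / sqrt(|Sa| |Sb|) ),  S = (Sa+Sb)/2.

The multi-class statistic sums squared JM over all unordered class pairs
with prior weights from training-pixel counts. Two weighting conventions are
implemented: the default sqrt(P_i P_j), under which the statistic is bounded
by 4 * sum_{i<j} sqrt(P_i P_j) (= 16 for nine equal priors) and which is the
only convention compatible with published nine-class values in the 10–12
range; and the literal product P_i P_j (bound < 2 for nine classes), kept as
a selectable option and recorded in every report. Ill-conditioned
covariances are ridge-lifted by 1e-6 * trace/d on the diagonal, with a
warning; this keeps exact duplicates and near-degenerate classes computable
without visibly moving well-conditioned results.

## Red-edge indices

The ten-index registry (NDRE, NDVIre1, NDVIre2, CIre1, CIre2, MCARI1,
MCARI2, TCARI1, TCARI2, MTCI) evaluates the published formulas verbatim in
float64. Under these definitions TCARI1/2 are exactly three times MCARI1/2 —
the pairs are perfectly collinear, which is why the stepwise-discriminant
scatter matrix over all ten indices is singular by construction and is
ridge-regularized with a warning. Pixels where a denominator vanishes (or an
input is nodata) are masked, never substituted; the masked count is logged.

## GLCM texture

Texture uses a 3 x 3 sliding window per pixel. The methodology fixes only
the window and the eight measures (Mean, Variance, Homogeneity, Contrast,
Dissimilarity, ASM, Entropy, Correlation); the remaining choices are the
package's, all config-exposed:

* 64 gray levels, linear min–max quantization over the band's valid pixels;
* four unit offsets (0°, 45°, 90°, 135°), symmetrized and pooled *before*
  normalization, making the measures direction-invariant;
* reflect padding at image edges; windows touching nodata are masked;
* Correlation of a zero-variance window is defined as 1 (a constant window
  is perfectly self-correlated), with the degenerate count logged.

The per-pixel image computation is vectorized: pair-local measures are
window means over shifted-image arithmetic, and the distributional measures
(ASM, Entropy) come from run lengths of per-window sorted co-occurrence
codes, using sum_runs c^2 = sum_elements (2r - 1) and
sum_runs c ln c = sum_elements [r ln r - (r-1) ln(r-1)] where r is the
element's rank within its run. This is algebraically identical to building
each window's co-occurrence matrix, and the tests verify bit-level agreement
with the explicit-matrix routine window by window.

PC1 is computed per band over the whole image's valid pixels: the eight
measures are standardized, zero-variance measures dropped (loading reported
as 0, with a warning), and the sign fixed so the loading on Mean is
non-negative. Because the Mean measure tracks the local band mean, the PC1
texture layer carries some spectral signal along with roughness.

## Feature importance

Two scores per feature:

* **Stepwise discriminant F.** Classical Wilks'-lambda stepwise selection:
  the partial F-to-enter of candidate x given entered set S is
  ((Lambda_S/Lambda_{S+x}) - 1) (n - g - |S|)/(g - 1); the best candidate
  enters at F >= 3.84, entered features leave at F < 2.71 (the conventional
  thresholds of classical discriminant-analysis software; both
  configurable). With S empty this reduces exactly to the one-way ANOVA F,
  which the tests assert. A feature's headline score is its F-to-enter at
  its entry step; never-entered features report their final-step candidate
  F, flagged.
* **Mean decrease Gini.** Impurity importance of a seeded 500-tree random
  forest (importance ranks stabilize more slowly with tree count than
  accuracy does, hence larger than the 100-tree classification forest),
  normalized to sum 1 — the convention under which published importance
  columns sum to about 1.

Top-k selection sorts by the chosen score with ties broken by the other
score, then by name.

## Classification schemes and random forest

All twelve schemes share the four base bands (R, G, B, NIR) and add: A-2/A-3/
A-4 the red-edge bands; B-1/B-2/B-3 the texture PC1 of RE1 and/or RE2 and
B-4 that of NIR; C-1..C-4 exactly one of CIre1, MTCI, NDRE, NDVIre1 (the
four indices both importance methods select from the published scores).
Classification is per pixel with a seeded random forest: 100 trees,
sqrt-of-features split candidates, no feature scaling (forests are
invariant to monotone per-feature transforms). Per-scheme seeds derive from
the master seed and the scheme id, so schemes are independent and the whole
suite is reproducible bit for bit.

## Accuracy assessment

OA = 100 trace/total; PA and UA are per-class recall and precision in
percent; kappa uses marginal-product chance agreement; F1 is the harmonic
mean of UA and PA evaluated directly on the percent scale (the published
tables confirm this reading of the formula's trailing percent annotation).
Classes with an empty reference row or predicted column report PA/UA/F1 as
missing, not 0. McNemar's test uses pixel-level pairing over validation
pixels, chi2 = (f12 - f21)^2/(f12 + f21) with 1 df and *no* continuity
correction — the convention that exactly reproduces the published
comparison table — with significance at chi2 >= 3.84; pixels nodata in
either map are excluded.

### A note on the published comparison table

The published reference table shipped for the chi-squared consistency check
contains 23 paired comparisons. Twenty of them (including every worked
example) reproduce to within 0.01 from their printed discordant counts.
Three rows (analyses 9, 10 and 22) are internally inconsistent: no rounding
of their printed counts yields their printed statistic. The acceptance test
parametrizes per row, so those three rows fail visibly rather than being
silently excluded; the package's arithmetic is validated by the twenty
self-consistent rows.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:

* a field mosaic (anisotropic Chebyshev-metric Voronoi cells around random
  seeds — contiguous, rectangular-ish fields), each field carrying one of
  nine land-cover classes; class field-shares follow the reference survey's
  pixel proportions with a 4% floor so minority classes always receive
  enough contiguous area to host their sample polygons;
* per-class 8-band Gaussian reflectance whose means separate mainly in the
  NIR/RE1/RE2 region; the RE1 means are deliberately non-monotone in NIR so
  the 710 nm band carries separability NIR does not already provide, while
  RE2 tracks NIR closely — planting the "RE1 adds more than RE2" effect the
  downstream analyses are expected to recover;
* spatial texture by Gaussian smoothing of the per-pixel noise at a
  class-specific scale (smooth_sigma, pixels). The smoothing is
  variance-normalized: it sets the autocorrelation length without shrinking
  the marginal covariance, so estimated signatures converge to the planted
  parameters for any sigma. Smoothing does inflate the variance of a sample
  *mean*; recovery tests therefore use an effective sample size of
  n / (1 + 4 pi sigma^2), the white-noise/Gaussian-kernel correlation-area
  correction;
* reflectance clipped to [0, 1] (clip fraction logged), an optional uniform
  nodata fraction, square sample polygons placed fully inside single-class
  fields and split 1:1 into train/validation *by polygon*.

One master seed drives documented per-stage generators (stage-name hashing),
so every stage is independently reproducible.

What the scenes do **not** emulate: radiative-transfer physics, phenology or
any temporal dimension, mixed pixels and field-boundary gradients, clouds or
shadows, georeferencing. Consequently, passing tests demonstrate that the
pipeline recovers effects of the kind the methodology targets — they say
nothing about absolute accuracy levels on real imagery, and the published
accuracy magnitudes are data-dependent and are not reproduction targets.

## Problem sizes

Unit and property tests run scenes of 96–192 px with reduced forests
(25–60 trees), sized so the full suite completes in well under a minute of
scene computation per test; the acceptance script runs the complete
twelve-scheme experiment on a 256 x 256 scene with 16 polygons per class and
100-tree forests. These are the package's default study scales; all are
plain parameters.

## Known limitations

* McNemar significance treats validation pixels as independent; spatially
  autocorrelated errors make the test anticonservative. This mirrors the
  standard practice the package reproduces and is deliberately not
  corrected.
* The stepwise-discriminant variant (thresholds, entry statistic) follows
  the conventional defaults; other software may report univariate rather
  than partial F values, which coincide only for the first entered feature.
* Texture PC1 mixes roughness with local mean signal (see above); schemes
  B-1..B-4 should be interpreted accordingly.
* The generator's field geometry yields convex, compact fields; real
  agricultural parcels are more irregular, which mainly affects texture
  statistics near boundaries.
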