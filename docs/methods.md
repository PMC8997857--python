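# Methods

This note documents the models, numerical choices and known limitations of
`zotrad`. It is the package's own account of its procedure; every number it
mentions is computed by the test suite or `scripts/acceptance.py`.

## Zone-of-transition model

The tumour/parenchyma interface is modelled as a *band*, not a curve. Two
assumptions drive the detector:

* the true edge is the crest of the gradient magnitude, so a manual border
  pixel can be relocated by marching along ± the local gradient direction
  (within a coarsely dilated search band) to the magnitude maximum;
* the gradient profile through an edge pixel — along the gradient direction
  and at ±45° to it — is bell-shaped, and the spatial extent of the
  transition is delimited by the two local minima flanking the central peak.

On smooth synthetic edges the profile tails decay monotonically and have no
strict interior minimum, so the walk outward from the peak also terminates
at the first sample at or below a **noise floor** (default 10% of the 95th
percentile of border gradient magnitudes). A line is *reliably detectable*
only if its peak clears the floor and both ends are found before the
profile runs out; pixels in flat surroundings are therefore undetectable,
and if fewer than half of the border pixels have any detectable line the
case is rejected as "ZOT undetectable" rather than silently approximated.

The band is the union of the *interiors* of the detected min-to-min
segments — the minima themselves mark where the transition has died out.
Tangential gaps left by undetectable pixels are bridged by morphological
closing with a disk whose radius is the median detected half-width; a
distance clamp then removes anything the closing placed farther from the
refined border than the detected transitions reach, so the band can never
swallow the lesion core. The result crosses the border by construction
(positive overlap with both the tumour interior and exterior) and is
anisotropic: wide where the image transition is gradual, ~3 px (sampling
limited) at an analytically sharp edge.

Defaults, all configurable: gradient operator = Gaussian-smoothed central
differences with σ = 1 px (no operator is canonical for this task); coarse
dilation radius 10 px; gradient-line half-length 15 px. The ±45° offsets
are taken relative to the *local gradient direction*, not the image axes.
ZOT detection is 2-D, on the slice with the largest tumour area (ties break
to the lowest index).

## Feature catalogue

654 named first-order features per nodule. Local features are computed on
(2r+1)² neighbourhoods (default r = 2) intersected with the ROI;
neighbourhoods with fewer than 4 ROI pixels are excluded. The 7 tumour
local features are mean, variance, skewness, kurtosis, entropy, uniformity
and median; the ZOT adds range, mean absolute deviation and RMS (10), and
is computed on gradient-magnitude images. The 12 global descriptors are
mean, SD, median, IQR, min, max, range, skewness, kurtosis, entropy,
uniformity and the 90th percentile. Only skewness (S), entropy (E) and
uniformity (U) of these sets are pinned down by the published signature
names; the remaining members were chosen once to honour the 7/10/12
cardinalities with the most standard first-order statistics, and both sets
are config-overridable.

Entropy and uniformity use 64 equal-width bins spanning the region's
min–max, log base 2 — a standard first-order radiomics convention stated
explicitly for reproducibility. Constant regions give entropy 0 and
uniformity 1; degenerate moments (zero variance) give skewness and kurtosis
0 by convention. A/V ratio features go missing (NaN, logged) when the
venous value is below 1e-9 in magnitude; missing values are median-imputed
at normalisation time, with the imputation value learned on training data.

## Selection

Contrast stretching maps each feature linearly from its [2.5th, 97.5th]
percentile range to [0, 1] (clipping outside), followed by z-scoring; all
parameters are stored and re-applied, never re-fit, on held-out data.
LASSO uses 3-fold cross-validation over the penalty grid with observation
weights n/(2·n_class), ranking retained features by |coefficient|; at most
the top 25 enter the quadruple search (the study-scale retained count).

The quadruple search discards combinations containing any pair with
|Spearman ρ| > 0.3. The redundancy correlation is measured **within class**
(the larger of the two class-conditional |ρ|): on a pooled sample, any two
features that each separate the classes strongly are correlated through
the label alone, which would disqualify exactly the pairs a signature
wants; the within-class measure targets redundancy beyond the class
signal. Pooled correlation is available via `corr_scope="pooled"`.

The rank-sum test is univariate, so a combination-level score must be
chosen: each surviving quadruple is scored by the **worst (largest)** of
its four member-wise Wilcoxon rank-sum p-values, Holm–Bonferroni corrected
across all surviving quadruples at α = 10⁻³, lowest significant score wins,
ties break by enumeration order. The score rule is recorded in every
result. When nothing is significant the library raises a "no signature"
error; the pipeline, to keep null cohorts runnable end-to-end, falls back
to the best-scoring quadruple explicitly flagged `significant=False`.

## Oversampling

Per class and per signature feature, a normal-kernel KDE with a
diffusion-equation (DCT fixed-point) plug-in bandwidth; Silverman's rule is
the fallback for n < 20 or when the fixed point is not bracketed. New
instances are drawn by Latin hypercube sampling — exactly one sample per
marginal probability stratum — mapped through each KDE's quantile function
(grid-interpolated CDF inversion), with Iman–Conover rank reordering toward
the class's initial Spearman correlation matrix. Across `n_runs` LHS
repetitions (default 10⁵; tests and the demo configs use ≤ 500) the kept
run minimises the cost

    f(x) = ∏_{i<j} dρ(i,j)² ,

the product of the squared upper-triangle entries of the
oversampled-minus-initial correlation difference. The product form is
implemented as printed even though it has an absorbing zero (one perfectly
preserved pair zeroes the cost regardless of the others); a sum-of-squares
alternative sits behind `cost="sum"`, default off. Real rows pass through
byte-identical and keep a `real` flag. KDE fitting and oversampling operate
on the normalised feature scale.

The MSE diagnostic compares class-conditional histograms (20 equal-width
bins over the pooled range, density-normalised) against the KDE at bin
centres, before and after augmentation.

## Classifier protocol

Stratified split preserving class proportions: per-class training counts
are rounded to the nearest integer and reconciled to the target total by
largest remainder — with 169 = 62/107 and fraction 117/169 this gives
exactly 43/74 and 19/33. (A perfectly even 3-fold split of 43/74 is
impossible; stratified folds differ by at most one sample per class.)

Each of the default 100 CV runs draws a fresh stratified 3-fold partition;
every (fold × cost) linear SVM uses class-prior-scaled misclassification
cost (balanced class weights) over the grid C ∈ {0.01, 0.1, 1, 10, 100}
(no canonical grid exists; this spans four decades). Models whose
internal-validation AUC exceeds their training AUC are discarded — the
overfit filter is implemented verbatim in that direction, unusual as it is,
and `invert_overfit_filter` switches it; the number discarded is logged. A
run whose fold-models are all discarded contributes no candidate. Final
selection refits each candidate on the full training set and maximises
(training AUC, informedness at the Youden cut-off, enumeration order).

The radiomic score is a binomial-logit (Platt-style) mapping of the SVM
decision value, fitted on training outputs; the operating threshold is the
Youden cut-off on training scores. The published four-feature signature is
frozen in `classifier.REFERENCE_SIGNATURE` for score arithmetic and
regression tests; it is *not* a claim that those coefficients transfer to
other data.

### Protocol order and leakage

The development protocol this package reproduces selects the signature,
fits the KDEs and oversamples on the **full initial dataset before the
train/test split**; test rows therefore inform selection and augmentation.
The default faithfully reproduces this and stamps a `leakage_note` into
every report. `oversample_before_split=False` activates a leakage-safe
variant: the initial dataset is split first and every data-driven parameter
(normalisation, LASSO, quadruple search, KDEs) is fit on training rows
only. Null checks (permuted labels) are meaningful only in the safe mode —
under the faithful protocol even pure-noise cohorts score optimistically,
which is precisely the bias the flag documents.

## Evaluation

All rates come from explicit confusion counts; undefined denominators
return "undefined" (None), never NaN. The AUC confidence interval is a
stratified bootstrap percentile interval (2000 replicates by default), with
DeLong's asymptotic interval behind `method="delong"`. Hosmer–Lemeshow uses
deciles of risk with empty bins merged and χ² df = bins − 2; fewer than 3
usable bins is an error. Decision curves exclude pt = 1. Report rendering
mirrors clinical convention — percentages to integers, predictive ratios to
one decimal, I/PSI to two — while raw values are always retained;
PSI is additionally reported through the rounded PPV/NPV chain, since
0.71 + 0.87 − 1 = 0.58 while the raw value 0.585 rounds to 0.59.

## Phantom generator

Phantoms emulate the study conditions: an elliptical lesion (default
semi-axes 14 × 11 px at 1 mm/px, ≤ 3 cm equivalent) with core→background
intensity following a logistic profile in the signed distance to the
ellipse; `rim_width` is calibrated so the FWHM of the radial intensity
derivative equals it exactly (logistic scale k = rim/2·ln(3+2√2)), making
the ground truth recoverable by radial profiling. Arterial core 110 HU,
venous 90 HU, background 60 HU (hyper-enhancement then washout). Texture is
a stationary Gaussian random field (white noise smoothed at a 2 px
correlation length) with amplitude `texture_sd_core` inside and an extra
`texture_sd_rim` bump at the border, *shared between phases* (same tissue),
plus independent 3 HU white noise per phase. Cohort defaults encode the
class contrast: MVI+ texture SDs 18/22 HU vs MVI− 8/10 HU — the
heterogeneity ordering the classification problem rests on — with uniform
anatomical jitter on radii (±2.5 px), rim width (±2 px) and intensities
(±8/±5 HU). Manual masks perturb the true boundary radius with a 3–6 lobe
sinusoid of amplitude ≤ rim/2, emulating hand-drawn imprecision that border
refinement must undo.

What the phantoms do **not** emulate: liver anatomy, vessels, neighbouring
organs, CT reconstruction physics (beam hardening, streaks, anisotropic
voxels), multi-lesion interactions, or realistic inter-feature correlation
structure. Passing tests demonstrate that the algorithms recover planted
ground truth under controlled conditions — not clinical performance. The
default class contrast makes the synthetic classification problem much
easier than the clinical one; end-to-end phantom AUCs near 1.0 are a
parameter-recovery check, and the published real-data AUC (0.86 on the
external set) is not reproducible because the patient images are private.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen once:
phantom cohorts of 89 nodules (32/57) on 96×96 px slices; oversampling to
169 (62/107); LHS with 20–500 runs (the cost is a running minimum, so more
runs only improve it); 25–100 CV runs; 200–2000 bootstrap replicates;
50-repeat selection-recovery and 20-repeat MSE simulations. The library
defaults keep the full-scale values (10⁵ LHS runs, 100 CV runs, 2000
bootstrap replicates).

## Known limitations

* ZOT detection is single-slice 2-D; volumes contribute only through
  tumour-volume features.
* The refinement contour is filled via an angular sort around the mask
  centroid, which assumes a star-shaped lesion — adequate for HCC-like
  blobs, wrong for strongly concave shapes.
* The product-form LHS cost can be zeroed by a single preserved
  correlation pair; it is kept as the reference behaviour.
* Feature indices of the original study (e.g. which feature was "F63")
  depend on an enumeration order that is not recoverable; names, not
  indices, are the stable identifiers here.
* DICOM input is out of scope; NIfTI and PNG/TIFF are supported.
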