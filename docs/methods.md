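# Methods

This note records the modelling conventions, parameter choices and
numerical details behind `minkrad`, and what the synthetic phantoms do and
do not establish.

## Intensity normalization and thresholding

The grey-scale normalization that precedes thresholding is a tumour-wide
min–max map onto [0, 1]: `lo`/`hi` are the minimum and maximum raw
intensity over every ROI pixel of every slice.  A single tumour-wide scale
(rather than per-slice) keeps the threshold ladder a fixed partition of one
observed grey scale, so per-slice counts can be summed meaningfully.
Per-slice normalization can be emulated by passing single-slice images.
Consequences worth knowing:

- The spectrum is invariant to positive affine transforms of the input
  intensities (receiver gain, windowing), which is the point of
  normalizing.
- A constant-intensity ROI maps to all ones: every pixel is white at every
  threshold, the degenerate but well-defined limit of "threshold 1 is all
  white".
- Because the map is min–max, the *spread* of the interior texture is
  largely absorbed; what the spectrum sees is the *shape* of the intensity
  distribution and the spatial arrangement of values, not the raw SD.

Thresholds are evenly spaced, `t_i = (i − 1)/n` for `i = 1..n` with
`n = 11` by default: ten equal steps from the all-white image, with the
endpoint `t = 1` unused so the last binary image is generically non-empty.
A pixel exactly at threshold is white (the rule that makes `t = 0` all
white).  Pixels outside the ROI are excluded entirely — they are neither
black nor white, so the functionals describe the segmented region only and
the first-threshold perimeter is the ROI contour, not an image-frame
artefact.

## Minkowski functionals on the pixel complex

White pixels are closed unit squares; `count_cells` counts their union's
distinct faces/edges/vertices by marking lattice sites, so shared cells are
counted once.  The functionals are `A = p`, `U = −4p + 2e`,
`χ = p − e + v`.  Two conventions are implied and verified by the oracle
tests:

- White connectivity includes diagonal contact (8-connectivity): two
  squares sharing only a vertex form one connected region.
- Enclosed black regions (holes) use the dual 4-connectivity and must not
  reach the bounding frame.

`χ = p − e + v` then equals (white components) − (holes), and
`U = −4p + 2e` equals the number of unit edges with white on exactly one
side; both identities are enforced on thousands of random images against
independent labelling/edge-scan implementations.

Counts are summed over slices per threshold *before* applying the formulas
and the single normalization by the total ROI pixel count.  This yields one
spectrum per tumour and makes normalized area exactly the above-threshold
pixel fraction (hence 1 at the first threshold, which is why `nArea_1` is
dropped from the feature list).  Note that with pixel-count normalization
the genus values are small fractions; descriptions of heterogeneity moving
the genus "away from unity" refer to the unnormalized count scale.

Size features are reported in pixel units (pixel count and edge count);
millimetre conversions via the spacing metadata are opt-in and never touch
the normalized spectrum.  Signal-intensity statistics are computed on the
raw intensities pooled over slices and then divided by the reference-region
mean; SD is the population SD.  The >1 cm cyst-exclusion rule used when
lesions are segmented is a segmentation-time convention: the library treats
the supplied mask as authoritative.

## Selection and classification

Feature selection runs on the raw features; the selected columns are then
z-scored with training-cohort statistics (applied unchanged to any test
cohort; zero-variance columns are dropped with a warning).

**t-test selection.**  Two-tailed unpaired Student t-tests (pooled
variance), keep `P < 0.05`.  No multiple-testing correction is applied by
default — the threshold is deliberately permissive, feeding a regularized
classifier — but a Holm flag exists.

**LOOCV grid SVM.**  RBF kernel; default grid `C ∈ 2^{−5,−3,…,15}`,
`γ ∈ 2^{−15,−13,…,3}` (standard LIBSVM practice; the original grid is
unreported, so the default is declared, not inferred).  For each pair the
LOOCV accuracy is computed exactly; ties break to the smallest `C`, then
the smallest `γ`.  The final model is refit on all rows at the chosen pair;
the held-out predictions and decision values at that pair are stored and
all reported metrics are recomputable from them.  The protocol tunes and
reports on the same LOOCV — the honest-looking but optimistically biased
variant that matches the method being reproduced; the stored decision
values let a user nest it if desired.

**Random-forest selection.**  Breiman out-of-bag permutation importance:
1000 bootstrapped `sqrt`-feature trees; per tree, the accuracy drop on its
out-of-bag rows when one feature column is permuted; averaged over trees.
(Permutation importance measured on training rows is degenerate here — a
deep forest classifies its training rows perfectly no matter which single
column is shuffled.)  Features above the mean importance are kept, a
parameter-free cut-off; if nothing clears it (all-noise tables) the single
top-importance feature is kept so the downstream fit remains defined.

**Lasso.**  L1-penalized logistic regression minimizing
`−(1/n)·loglik + λ‖β‖₁` with an unpenalized intercept.  Solver: outer IRLS
reweightings, each building the Newton-type quadratic surrogate (working
response and weights, weights floored at 1e−5, linear predictor clipped at
±30) and minimizing it exactly by coordinate-wise soft-thresholding
(compiled kernel; the inner solve may need many thousand sweeps when
features are strongly correlated, as radiomics spectra are).  Convergence:
no coefficient moves by ≥ 1e−6 across a reweighting, with a cap of 10⁴
reweightings.  On separable data with vanishing penalty the maximizer is at
infinity; coefficients are capped at 30 on the standardized scale and the
fit is flagged non-converged.  λ is chosen from a log-spaced grid
(10⁻³…10¹, 17 points) by LOOCV accuracy, ties resolved to the larger
(sparser) penalty; each fold's path is fit descending with warm starts.

**Metrics.**  Accuracy = (TP + TN)/(TP + FP + TN + FN); sensitivity is
recall of progression (the positive class throughout).  Binomial intervals
use the Wilson score method, whose bounds are exactly 0/1 at boundary
counts.  AUC is the Mann–Whitney statistic of the held-out decision values
(ties half-credited).  Every fit records its seed; serialized models store
the scaled training matrix (SVM) or the weights (lasso) plus the scaling
statistics, so predictions are bit-reproducible across processes.

## The phantom generator

Phantoms realize, with independent knobs, the four morphological axes that
separate the classes: size (`base_radius`), boundary irregularity
(`frond_amplitude`, `frond_modes`: a cosine-series perturbation of a
star-convex boundary, coefficients normalized so the boundary stays
simple), interior texture (Gaussian random field — white noise filtered by
an isotropic Gaussian of width `texture_corr_len` px, scaled to relative SD
`texture_sigma`), and dark foci (Poisson-count circular depressions of
relative depth `dark_focus_depth`, emulating the microhaemorrhage/necrosis
interpretation of low T2 signal; they drive `SImin` down).  Slice radii
follow a spherical-cap profile; a rectangular "white matter" reference
strip at `wm_mean` (3% noise) sits outside the lesion on the first slice;
the lesion base intensity is 1.6 × `wm_mean` (a T2-hyperintense lesion).

Default class conditions (chosen once as a plausible contrast of the
described phenotypes, not fitted to anything): progression
`base_radius 14, frond_amplitude 0.35, texture_sigma 0.30,
texture_corr_len 1.5, dark_focus_rate 1.2/100 px, dark_focus_depth 0.6`;
pseudoprogression `10, 0.10, 0.15, 3.0, 0.3, 0.25`; both on a 64×64 canvas,
3 slices, `wm_mean 100`.  Under these conditions progression phantoms have
larger area, lower minimum signal intensity and stochastically higher
mid-threshold normalized perimeter (rank-tested at n = 50 per class), and a
default 10 + 10 cohort is classified essentially perfectly by both
strategies.

What phantoms do **not** establish: they are not MR simulations (no
k-space, coil, relaxation, partial volume or scanner-field effects — the
known 1.5 T/3 T MF discrepancy is documented, not modelled), their textures
are stationary Gaussian fields rather than tissue, and the class contrast
is by construction along the axes the features measure.  Passing tests
therefore demonstrate that the pipeline recovers a planted morphological
contrast of the described kind — not clinical performance.

The sphere reference curve (`sphere_reference`) uses the continuous
slicing limit: a sphere of radius R sliced at pitch d has summed
cross-section (4/3)πR³/d and summed circumference π²R²/d; eliminating R
maps total area to the total perimeter a sphere-shaped lesion would have.
Digital perimeters exceed Euclidean ones (by up to 4/π for smooth convex
shapes), so rasterized discs sit slightly above the curve; the utility is a
reference shape, not a digital-bias correction.  Default pitch is 1 pixel
unit; the clinical slice pitch (6 mm thickness + 1 mm gap) can be passed
via the spacing metadata.

## Problem sizes and determinism

The shipped tests and the acceptance script use 10 + 10 phantom cohorts on
64×64×3 grids, 1000 random images up to 12×12 for the formula oracles, and
50 per class for the generator's rank-test self-check — sizes at which
every quantity is recomputed from scratch in seconds while leaving the
statistical checks well-powered.  All randomness flows from explicit seeds
(phantom seeds are drawn deterministically from the cohort seed); the CLI
refuses stochastic commands without `--seed`.

## Known limitations

- 2D functionals on a slice stack, not 3D Minkowski functionals.
- The LOOCV-tuned-and-reported protocol is optimistically biased; treat
  reported LOOCV accuracies as the method's own convention, and use an
  independent cohort (as `scripts/acceptance.py` does) for honest test
  error.
- Min–max normalization is sensitive to single extreme ROI pixels, which
  compress the rest of the scale; the genus/perimeter spectra inherit
  that sensitivity.
- The t-test selector ignores feature correlation; selected sets are
  redundant by design (the spectra are strongly autocorrelated across
  thresholds).
- DICOM ingestion, bias-field correction, registration and automated
  segmentation are out of scope; masks are taken as authoritative.
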