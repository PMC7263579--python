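# Methods

## Unwrapping model

Each short-axis slice provides a T1 pixel grid (ms), closed endocardial and
epicardial contours (ordered 0-based (x, y) pixel coordinates, x = column),
and one landmark at the inferior RV-insertion point. The LV center is the
endocardial-contour centroid. For each of `cols` angular positions at
`(c + 0.5)/cols` of a full turn from the landmark angle — proceeding
clockwise in displayed-image orientation (y down, i.e. increasing
`atan2(dy, dx)`) — the endo and epi border radii are found by intersecting
the ray from the center with each piecewise-linear contour (nearest
positive intersection). `rows` samples are placed at fractional depths
`(r + 0.5)/rows` between the two radii, so all samples are strictly
interior; values are bilinearly interpolated. Row 0 is the endocardial
side; the map column 0 starts at the landmark, matching the convention
that the bottom-left corner of the rectangle is the landmark on the
epicardial border. Five slices stack base (top) to apex (bottom) into a
`(5·rows) × cols` map.

Constraints and failure modes: `cols = 6·rows` always (six segments per
slice at every preset: R16 = 16×96, R32 = 32×192 default, R64 = 64×384); a
ray that misses a contour or a wall thinner than ~1 px raises an error
naming the angle. Rasterization (for the global-T1 baseline) classifies
pixel centers strictly inside the epicardial polygon and not strictly
inside the endocardial polygon; crossing contours are rejected, identical
contours yield an empty mask and fail at the unwrap stage. The transform is
not area-preserving — radial stretching weights all depths equally — so the
unwrapped-map mean only approximates the pixel-mask mean (within 1 % on
smooth fields, verified by test).

## Texture features (152)

* **Histogram (10).** Mean; population variance (1/N); skewness and
  kurtosis as standardized 3rd/4th central moments (kurtosis is *not*
  excess: a symmetric two-point distribution gives 1); standardized central
  moments of order 5–10, `m_k/σ^k`. Zero variance ⇒ all standardized
  moments defined as 0.
* **Quantization.** GLCM/GLRLM operate on an equal-width min–max binning of
  the stacked map into 32 levels (`floor(n·(v−min)/(max−min))` clipped;
  constant map ⇒ level 0 everywhere). The level count is a free choice —
  nothing in the feature definitions fixes it — taken as 32 so the
  co-occurrence matrices stay well-populated on a 160×192 map; it is
  exposed in the configuration. Min–max binning makes these families
  invariant to adding a constant to the map.
* **GLRLM (11 × 4).** Run-length matrices count maximal same-level runs
  along 0°, 45°, 90°, 135° (image convention: 45° = bottom-left→top-right
  diagonals, 135° = top-left→bottom-right). Gray-level weights use `i + 1`
  with levels from 0, so low-gray-level emphasis features never divide by
  zero. Run percentage divides by the pixel count of the map.
* **GLCM (6 × 10).** For each displacement d = 1..10 px, symmetric
  co-occurrence counts are pooled (summed) over the four directions —
  the feature count forces aggregation over directions, and pooling
  counts was chosen over averaging per-direction feature values — then
  normalized. The diagonal offset at displacement d is (±d, ±d), i.e. d
  pixel *steps* along the direction, consistent with the run-length
  directions (not d Euclidean pixels rounded). Homogeneity2 is implemented
  as the inverse difference moment `Σ p/(1+(i−j)²)`; the name is ambiguous
  among inverse-difference variants and this choice is flagged rather than
  asserted. Entropy uses log2 with 0·log 0 = 0; correlation is defined as 0
  when a marginal SD vanishes; Sum of Squares is the variance of the
  marginal, `Σ (i−μ)² p`.
* **LBP (38).** Rotation-invariant uniform codes with P = 36 circular
  neighbors (P + 2 = 38 bins) at radius R = 2 px (R unstated upstream;
  default documented and configurable). Neighbors are sampled bilinearly;
  codes are computed only for pixels whose full neighborhood lies inside
  the map; a neighbor counts as 1 when `neighbor − center ≥ −1e−9·max(1,|center|)`,
  so exact ties (constant map) give the all-ones pattern. Bins are labelled
  LBP(1)…LBP(38): bin b holds code b−1 (uniform codes 0..36 by number of
  ones, bin 38 = non-uniform).

Feature names are canonical strings — `GLN(135)`, `SRHGE(0)`,
`Contrast(d3)`, `LBP(8)` — in a fixed order (histogram, GLRLM, GLCM, LBP),
so selected features are addressable in every report. All 152 features are
verified against independent brute-force oracles (explicit pair loops, run
enumeration, naive per-pixel LBP) at 1e−10 relative tolerance.

## Selection, classification, texture index

Sequential forward selection greedily adds the feature maximizing
stratified 10-fold CV accuracy of a linear SVM (C = 1), ties broken toward
the lowest feature index, stopping at k = 7 (an optional no-improvement
early stop exists; the stopping rule is otherwise a fixed k). Fold
assignment is seeded and shared by all candidate evaluations of a run.
Normalization is mean/variance scaling fit on the training folds only; a
`paper_mode` flag reproduces one global normalization of the whole table
(the leakier variant some studies use).

Evaluation pools out-of-fold predictions of a stratified 10-fold CV into
one confusion matrix. SVMs use one-vs-one voting with one-vs-all-shaped
decision scores retained for ROC; KNN uses k = 5; the tree ensemble is a
200-tree random forest — hyperparameters are defaults, documented and
configurable, not tuned. One-vs-all AUCs use the Mann–Whitney estimator
with DeLong placement-value variance for normal CIs (clipped to [0, 1]);
paired AUCs are compared with the two-sided DeLong test with midranks for
ties (identical score vectors ⇒ Δ = 0, p = 1). Baselines mirror the texture
classifier on a single global-T1 feature and on the 30 segmental means
(6 column blocks × 5 slices, block 0 at the landmark). The texture index is
an OLS fit (minimum-norm when underdetermined) of a ±1 cohort coding on the
selected features. t-SNE (seeded, PCA init, perplexity min(30, (n−1)/3)) is
visualization plumbing only.

## Reproducibility statistics

ICC uses the two-way mean squares: consistency single-measure
`(MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error)` by default, with
the absolute-agreement single-measure variant behind a flag (the two-way
"mixed" family admits both; consistency is the default here and the choice
is cross-checked against `pingouin` in tests). Zero between-subject
variance returns 0 with a warning. Bland–Altman reports mean difference and
±1.96 sample-SD limits of agreement. Observer variability is emulated by
smooth seeded radial contour jitter (per-point Gaussian noise smoothed
along the contour, rescaled to SD 1 px by default); the jittered
endocardium is clamped to stay ≥1.5 px inside the jittered epicardium, as a
human re-drawing would never cross the borders.

## Synthetic phantoms: what they emulate and what they do not

Each subject is five slices of an annular myocardium (mild eccentricity,
endocardial radius tapering 26→18 mm base→apex, per-slice center drift) on
a 128×128 grid of 2.1 mm pixels. The subject's global T1 is drawn from the
cohort distribution (1071±32, 1096±38, 1123±38 ms); after texture and
Gaussian pixel noise (SD 25 ms) are painted, the field is shifted so the
myocardial mean equals the draw exactly — cohort statistics are recovered
by construction. Textures: control is homogeneous; HCM gets 2–5 elliptical
high-T1 patches (+120 ms nominal) inside a septal sector whose wall is
thickened by up to 7 mm, one patch per angular bin so the drawn count is
realized as disjoint regions; DCM gets thresholded smoothed-noise clusters
(+60 ms) plus extra uncorrelated noise (SD 15 ms). Values are painted 4 px
beyond the contours (standing in for surrounding tissue) so border
interpolation — and jittered contours in the reproducibility experiment —
never sample background zeros. All randomness flows from one master seed
through per-subject `SeedSequence((seed, index))` substreams, so subjects
are reproducible independently of generation order.

What passing tests show, and do not show: the phantoms guarantee the
pipeline's mechanics (geometry, feature math, selection, statistics) and
the *direction* of the headline effect — texture features separate the
cohorts far better than global T1, which overlaps by construction. They do
not calibrate absolute performance: phantom textures are cleaner and more
stereotyped than myocardial fibrosis, so near-perfect phantom accuracies
overstate clinical accuracy, and quantities that depend on realistic
between-subject texture variance are not reproduced. Two concrete cases:
the strong positive correlation between GLN(135°) and global T1 reported on
patients does not appear on phantoms (min–max quantization removes the mean
from GLN, and phantom texture variance is cohort-stereotyped; measured
correlation ≈ 0), and re-contouring ICCs of run-length features are low on
phantoms (between-subject spread ≪ jitter-induced change) even though
mean-T1-like features reproduce at ICC ≈ 1.

## Problem sizes and numerical choices

Analysis drivers and tests run at desk scale chosen for fast iteration:
30/30/30 subjects in `analysis/`, 50/50/50 for the main acceptance
experiment, 20/20/20 for the three-preset resolution sweep, 12 subjects for
re-contouring ICC, 200 per cohort for mean-recovery checks. Feature
extraction of one 160×192 stacked map takes well under a second; a full
pipeline run (extract + select + evaluate) on 150 subjects takes a couple
of minutes on one core. Oracle comparisons use 1e−10 relative tolerance;
geometric equivariance tests use fixtures whose pixel centers stay >0.05 px
from contour boundaries so polygon and analytic classifications cannot
disagree. Degenerate inputs (constant maps, zero variance, single-class
labels, walls thinner than the sampling grid) are either given fixed
documented conventions or rejected with named errors, as listed above.

## Known limitations

* 2-D per-slice texture only; no volumetric descriptors, wavelet or
  fractal families.
* The unwrap step assumes star-shaped contours about the endocardial
  centroid — true for phantoms and typical LV delineations, not for
  pathological shapes.
* No MRI signal simulation (inversion-recovery fitting, motion, partial
  volume); the phantom paints tissue values directly.
* Classifier hyperparameters are sensible defaults, not tuned; phantom
  accuracies saturate, so comparisons between the four classifiers are
  uninformative at phantom scale.
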