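# Methods

This package implements a dual-phase contrast-enhanced MRI (CE-MRI)
deep-learning-radiomics workflow for three-class differentiation of
liver lesions — hepatocellular carcinoma (HCC, class 0), dual-phenotype
HCC (DPHCC, class 1) and intrahepatic cholangiocarcinoma (ICC, class 2)
— together with a synthetic phantom generator that makes every stage
testable offline. This note documents the models, the numerical choices,
and what the phantom does and does not emulate.

## Phantom cohorts

Real multi-center CE-MRI cohorts for this task are not shareable, so the
generator plants exactly the imaging axes that radiologists use to
separate the three entities:

* **Margin irregularity** — the lesion is a sphere whose radius is
  modulated by a smooth random angular field; the per-class amplitude
  (mm) controls how irregular the boundary is. DPHCC-like lesions get
  the largest amplitude (irregular margins are characteristic), HCC the
  smallest.
* **Capsule** — with a per-class probability, the one-voxel boundary
  shell of the lesion is brightened by a fixed +30 offset in both
  phases (HCC lesions are typically capsulated; DPHCC typically not).
* **Enhancement pattern** — per-class arterial-phase (AP) and
  portal-venous-phase (PP) mean offsets over a homogeneous background
  organ at intensity 100: the defaults are hyperenhancement with PP
  washout for HCC (+45/−10), intermediate for DPHCC (+30/+5), and weak
  AP with progressive PP enhancement for ICC (+10/+20).
* **Internal texture** — a correlated Gaussian random field inside the
  lesion with per-class correlation length (2.0/3.5/5.0 mm) and
  amplitude (6/10/14), so texture-matrix features carry class signal.
* **Noise** — additive white Gaussian noise (sd 5) everywhere.

The default grid is 40×40×32 voxels at 1×1×1 mm with lesion radii drawn
uniformly from 6–10 mm and the lesion centre jittered by up to ±2 mm.
These sizes keep a 300-case, two-phase experiment with the full
1781-feature extraction comfortably on one CPU; they are the package's
benchmark scale.

Setting all per-class vectors equal (`PhantomSpec.null`) removes every
class signal: labels are then independent of the images, and a correct
pipeline must perform at chance. `PhantomSpec.strong_effect` (the
constructor defaults) is the documented strong-effect condition under
which the combined radiomics model is expected to reach macro-AUC ≥ 0.9
on a held-out 20% split.

Two-reader delineation variability is emulated by perturbing the mask
boundary with a smooth random offset field bounded by
`reader_jitter_mm` (inter-reader) and half that bound (intra-reader
repeat, which is typically tighter). The perturbation moves the signed
distance function, so it produces coherent dilations/erosions rather
than voxel noise. The phantom does **not** emulate anatomy (other
organs, vessels), MRI physics (bias fields, k-space artifacts),
inter-scanner harmonisation problems, or inter-phase misregistration —
AP and PP are generated on the same grid, as the pipeline assumes
aligned phases. Passing tests therefore demonstrate the machinery's
correctness and sensitivity, not clinical performance.

## Preprocessing

Fixed order: linear intensity normalisation to 0–255 (a constant volume
maps to zeros), classical CDF histogram equalisation (256 bins on the
0–255 range, per volume), isotropic resampling to 1 mm (linear for
images, nearest-neighbour for masks; output dimension =
round(dim·spacing/target)), and per-VOI fixed-bin-width discretisation
with bin width 5: level(x) = floor((x − min_in_mask)/width) + 1.
Discretisation is invariant to adding a constant to the VOI.

## Radiomics features (1781 per phase)

The inventory is 14 shape features computed once on the mask, plus 93
intensity/texture features — first-order (18), GLCM (24), GLRLM (16),
GLSZM (16), GLDM (14), NGTDM (5) — on each of 19 image types: the
original image and 18 derived images (8 one-level Haar wavelet
sub-bands LLL…HHH, Laplacian-of-Gaussian at σ = 2, 3, 4, 5 mm, square,
square root, logarithm, exponential, gradient magnitude, and per-slice
2-D local binary patterns, P=8, R=1, uniform). 14 + 19×93 = 1781. Each
derived image is re-discretised with the same bin width before texture
matrices are built.

Numerical choices:

* Texture matrices see only the tight bounding box of the mask; filters
  are applied on a box padded by 10 voxels so convolutions have
  context. This makes texture features exactly invariant under
  translation of the lesion within the grid.
* GLCM and GLRLM are computed per 13 unique 3-D directions at distance
  1; features are computed per direction and averaged (no distance or
  direction weighting). GLCM matrices are symmetrised and normalised
  per direction.
* GLRLM run counting sorts grid positions by (line identity, position
  along the line) once per grid shape, reducing maximal-run detection
  to change detection on a sorted sequence; the plan is cached.
* GLSZM zones use 26-connectivity (`scipy.ndimage.label`); GLDM uses
  α = 0 and counts in-mask 26-neighbours within the level tolerance;
  the matrix is indexed from dependence 0, while the feature formulas
  use dependence size j = d + 1 so that small-dependence emphases stay
  finite. NGTDM excludes voxels with no in-mask neighbour.
* The Laplacian-of-Gaussian is applied to the mean-centred volume: the
  truncated discrete kernel leaks a ~1e-4 fraction of any constant
  offset, and centring removes the DC component the operator should
  annihilate.
* Shape: enclosed volume and diameters come from the marching-cubes
  iso-surface of the raw binary mask (volume via signed tetrahedra,
  diameters via the convex hull of the surface vertices); surface area
  comes from the iso-surface of the mask smoothed with a 0.8-voxel
  Gaussian, which suppresses the voxelisation staircase that otherwise
  inflates the area of a smooth lesion by several percent (both
  estimates are within ~2% of the analytic sphere at radius 10 mm, and
  the smoothing falls back to the raw surface for lesions small enough
  to vanish under it). Axis lengths derive from the eigenvalues of the
  voxel-coordinate covariance (4·√λ).
* Degenerate single-level VOIs: features whose formula divides by zero
  (correlation-type GLCM terms, NGTDM contrast family) return 0;
  GLCM MCC returns 1 for a single-level matrix.

## Max-ROI slices and deep features

The axial slice with the largest tumor area (ties: lowest index) and
its −2, −1, +1, +2 neighbours are each cropped to that slice's minimum
bounding rectangle of the tumor (half-open, 0-based boxes; no margin is
added). An offset slice without tumor is substituted by the nearest
tumor-bearing slice in the same direction, with a warning — the
five-crops-per-case-phase contract always holds. Crops are taken from
the preprocessed volumes and exported as 8-bit PNGs.

Embedding backends are contracts on the penultimate-layer width: ViT
1024, vgg19 4096, googlenet 1024, inception_v3 2048 (input 224×224
except inception_v3 at 299×299). Two weight modes exist: `pretrained`
needs torch/torchvision and raises a clear error when they are absent;
`random` (the default) is a deterministic seeded filterbank — 16
zero-mean random 7×7 kernels, ReLU, 4×4 average-pool grid plus per-map
max and standard deviation, then a seeded Gaussian random projection to
the architecture's width with a tanh squashing. It is reproducible
across platforms, sensitive to image content, and enforces the
dimension contract, but carries no natural-image prior; the `pseudo`
backend is the same filterbank at a configurable width (default 64) on
64×64 inputs for fast experiments. Inputs are resized bilinearly,
min-max scaled to [0,1], and standardised with fixed channel constants
(0.485/0.456/0.406, 0.229/0.224/0.225). The five slice embeddings of a
case-phase are aggregated by the element-wise mean (permutation
invariant).

## Feature selection and fusion

* **ICC filter.** On (up to) 30 cases with two readers' masks and one
  reader's repeat, ICC(2,1) — two-way random effects, absolute
  agreement, single rater — is computed per feature for inter- and
  intra-reader pairs; a feature is retained only if both reach 0.8.
  Zero-variance features have undefined ICC and are dropped with a
  warning. The implementation is a vectorised ANOVA decomposition and
  is cross-checked against `pingouin.intraclass_corr` in the tests.
* **Z-scoring** uses training rows only (sample sd, ddof = 1); the
  fitted transform is applied unchanged to test rows, which therefore
  need not have zero mean.
* **LASSO.** One symmetric L1-penalised multinomial logistic model per
  feature block (a single λ, rather than three one-vs-rest fits), with
  loss (1/n)·cross-entropy + λ‖W‖₁ and unpenalised intercepts. The λ
  grid is 25 log-spaced points from λ_max (the smallest penalty with an
  all-zero solution, max |Xᵀ(Y − π̄)|/n) down to λ_max/100. Per λ,
  five-fold stratified cross-validated multinomial deviance gives a
  mean and standard error; λ_1se is the **largest** λ whose mean loss
  is within one SE of the minimum (the sparsest acceptable model), and
  the selected set is the features with any non-zero class coefficient
  after refitting on all training rows at λ_1se. The path is solved by
  FISTA proximal gradient with warm starts down the grid, a Lipschitz
  step from the power-iteration spectral norm (0.5·σ²_max/n), soft
  thresholding, and a 1e-5 relative-change stopping rule; coefficients
  agree with scikit-learn's saga solver to ~1e-4 in the tests. An
  empty selection falls back to an intercept-only (constant-feature)
  model with a warning.
* **Fusion.** Per-modality selection first, then concatenation
  (radiomics then deep, name prefixes keep the spaces disjoint), then a
  greedy scan in that fixed order dropping any feature with
  |Spearman ρ| > 0.9 against an already-kept feature, computed on
  training rows only. The retained set satisfies the ≤ 0.9 bound by
  construction, which the tests verify post-hoc.

## Splitting, classifiers, evaluation

Cases tagged `external` never enter training: they form the external
test set. The remaining pool is split 8:2 by stratified random
sampling: internal test size = ceil(0.2·n), apportioned across classes
by largest remainder of the proportional quotas, membership by seeded
within-class shuffle. A 306-case cohort with class sizes (108, 102, 96)
yields train 244 / internal test 62.

The classifier bank is SVM (RBF, Platt-scaled probabilities), logistic
regression (L2, multinomial), random forest (500 trees) and decision
tree (unlimited depth), all seeded. Evaluation reports the 3×3
confusion matrix, accuracy, macro precision/recall/F1 (unweighted class
means over the classes present), per-class one-vs-rest ROC AUC, their
unweighted mean (macro-AUC), micro-AUC over the pooled (case, class)
binary indicators, and a stratified case-level bootstrap percentile 95%
CI for the macro-AUC (2000 replicates by default; orchestrated runs use
500 and the end-to-end benchmark 200 to keep runtimes short). A class
absent from an evaluation set leaves its OvR AUC undefined; the macro
averages the present classes with a warning. Model ranking sorts by
macro-AUC, then accuracy, then F1.

The full inventory under one configuration is 3 radiomics models
(AP/PP/combined), 3 deep-feature models per backend, and 3 fusion
models per backend, each crossed with the configured classifiers;
`combined` concatenates the AP and PP feature blocks before selection.

## Design choices that were genuinely open

* Aggregating texture features over directions by feature averaging
  (not matrix merging); distance 1; GLDM α = 0.
* Haar as the wavelet family, one level.
* Mean pooling of the five slice embeddings.
* Per-volume (not per-slice) histogram equalisation.
* Multinomial rather than one-vs-rest LASSO; the one-SE rule taken in
  the sparse direction.
* ICC form 2,1 (absolute agreement) for both inter- and intra-reader
  stability.
* Bootstrap percentile CIs for AUC; macro averaging for precision,
  recall and F1.
* The 18-derived-image filter set: wavelet and LoG alone yield 1223
  features, so the six intensity/gradient/LBP image types are included
  to complete the conventional 1781-feature inventory; the set is
  config-switchable.

## Known limitations

* The random-weight deep backends validate dimensions, determinism and
  plumbing but not transfer-learning performance; with torch installed
  the same interface accepts pretrained weights.
* The phantom's class effects are free parameters chosen to be
  plausible, not estimates from any clinical cohort; absolute AUCs on
  phantom data do not predict clinical AUCs.
* Shape features assume isotropic resampling has already happened (the
  pipeline guarantees it).
* Exact numerical parity with any third-party feature extractor is not
  a goal; the matrix builders are verified against brute-force
  enumeration and the documented invariants instead.
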