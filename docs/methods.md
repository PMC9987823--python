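# Methods

`voxsparse` implements sparse representation learning for voxel-level spatial
transcriptomics: learning K components from a voxel × gene expression matrix,
scoring them against a labeled anatomy volume, compressing the gene lists
that build them, and training minimal marker-gene probes. This note records
the models, the numerical choices, and what the synthetic phantom does and
does not establish.

## Sparse filtering

The core learner is sparse filtering, fit from scratch. With the z-scored
expression matrix arranged as examples = voxels and inputs = genes, each
component j is a linear functional f_j(v) = w_j · x(v) passed through the
soft-absolute activation g(u) = √(u² + ε) (default ε = 1e−8, configurable).
The K × M activation matrix is normalized twice:

1. each feature row is divided by its l2 norm across voxels (this equalizes
   feature scales, enforcing dispersal and favouring lifetime sparsity);
2. each voxel column is divided by its l2 norm across features (mapping every
   voxel's representation onto the unit sphere).

The objective is the summed l1 norm of the doubly normalized matrix, which is
minimized exactly when every voxel's representation is one-hot — population
sparsity. Minimization is limited-memory BFGS (memory 10, gradient tolerance
1e−6, default 500 iterations; 300 for the phantom-scale analyses in the
tests and acceptance script, where the optimizer plateaus well before that).
The analytic gradient backpropagates through both normalizations and the
soft-absolute; it is verified against central finite differences in the test
suite (max relative error < 1e−4 on a 6-voxel × 4-gene instance).

**Initialization.** The default start point is the set of K-means centroids
of the expression matrix (10 restarts, seeded), plus small seeded Gaussian
jitter — the analog of the SVD initialization used by dictionary-learning
implementations. A pure standard-normal start (`init="random"`) is also
provided; it satisfies the same optimizer contracts but on the phantom its
basin of attraction varies strongly with the seed, whereas the centroid
start is deterministic given the seed and consistently reaches equal or
better objective values. The objective is scale-invariant (exactly so in the
ε → 0 limit), so the jitter scale does not matter beyond keeping rows
nonzero; the K = 1 centroid of z-scored data is the zero vector, which is
why jitter is always added.

**A structural property worth knowing.** On z-scored data every linear
feature has mean zero across voxels, so a feature that is high on a region
occupying fraction p of the mask must average −p/(1−p) of its peak
elsewhere. The soft-absolute rectifies that floor. When K equals the number
of regions and the regions tile the mask (p = 1/8 here), the objective is
genuinely lower for sign-antisymmetric *contrast* features — positive on one
region, negative on another, floors cancelling — than for one-region
features. The fitted components therefore mix one-region features with
two-region contrast features; 2-means thresholding of a contrast feature
overlaps either of its regions at Dice = 2/3, which is the observed ceiling
for the worst-recovered regions while the K-means parcellation built from
all components recovers the anatomy essentially perfectly (AMI ≈ 1). This
is a property of the objective, not of the optimizer: refining from the
planted ground-truth weights converges to a contrast solution with a lower
objective. On real atlas data the regime is different (hundreds of small
regions, K far below the region count), and there single-region features
dominate because the floor scales with region fraction.

## Comparison methods

PCA, kernel PCA (quadratic/cubic polynomial, RBF, sigmoid), FastICA, sparse
PCA, and dictionary learning are adapters over scikit-learn with the same
results container. Only sparse filtering is bespoke. Gene weights are taken
from each estimator's components (transposed to gene × K); kernel PCA has no
gene loadings and its weights field is explicitly absent rather than
back-projected. For dictionary learning the l1 penalty α acts on the voxel
activations; for sparse PCA it acts on the gene loadings. On the phantom,
feature sparsity of dictionary-learning components and weight sparsity of
sparse-PCA components are each non-decreasing in α over {0.1, 1, 10}, and
sparse PCA at α = 0 spans the PCA subspace.

## Preprocessing

Genes are z-scored across voxels with the population SD convention
(divide by n; fixed so serialized artifacts are bit-stable). Constant
columns are dropped with a logged warning by default and raise in strict
mode. The consistency filter ranks each gene by the Pearson correlation
between its profiles in two paired matrices and keeps the top
ceil(n · (1 − drop_fraction)); correlations are rounded at 1e−12 before
ranking so exact ties break by gene order, and degenerate (zero-variance)
genes rank last.

## Feature metrics

- **Dice matching.** Features are thresholded by 2-means on the scalar
  activations (both membership masks kept). Feature-centric matching
  (`match_feature_to_regions`) takes, per feature, the best region over both
  masks, ties to the smaller region id; region-centric matching
  (`region_feature_dice`) tabulates every region × feature combination so
  the best feature per region can be read off. Aggregate
  `unique_region_count` counts distinct matched regions over features.
- **Connected components** of the mean-level isosurface: marching cubes,
  vertex adjacency from shared triangle edges, graph component count. When
  embedding an in-mask feature into the full grid, out-of-mask voxels are
  filled with the feature's minimum so background never crosses the
  isosurface. A threshold outside the value range warns and returns 0.
- **Sparsities.** feature_sparsity = voxels / voxels strictly above the mean
  activation; weight_sparsity likewise over gene weights. "Above the mean"
  is strict, on signed values as produced by the method; both are ≥ 1 and
  equal the vector length exactly when one element is active.
- **Shannon entropy** (nats) of activations binned into 256 uniform-width
  levels over [min, max] (constant input → 0).
- **Spatial entropy**: a 3D extension of gray-level co-occurrence entropy.
  Values are quantized per volume to 16 uniform levels, co-occurrences
  accumulated over the 13 unique 3D neighbor offsets, symmetrized, excluding
  out-of-mask voxels, and the Shannon entropy of the normalized matrix is
  returned. Bin edges track the per-volume min/max, so both entropies are
  invariant to affine rescaling.

## Parcellation

K-means on the voxel × K feature matrix, 10 seeded restarts, best inertia
kept. AMI uses max-normalization of the mutual information; ARI is the
standard adjusted Rand index (both via scikit-learn, which is also what the
field uses for these scores). `sweep_k` tabulates (K, AMI, ARI, inertia).

## Compression

Genes are ranked across features by max |weight| (default; alternatives:
sum of |weight|, rank-sum), so each feature's top genes survive pruning —
consistent with compressing toward the single highest-ranked gene per
component. Each round keeps the top n genes from the *latest* fit, refits
sparse filtering and K-means with the same seed (a no-op round therefore
reproduces the reference fit bit-for-bit), and records AMI/ARI against both
the round-0 parcellation and the anatomy. K is held fixed; the voxel mask
never changes, so all comparisons are over identical voxel sets.

## Probes

For a feature matched to a region, the 10 genes with the largest absolute
weights (ties by gene id; an all-zero weight vector warns) are standardized
and used to fit an l2-regularized logistic regression (C = 1, the common
default) under shuffled, *stratified* 5-fold cross-validation — regions can
be a few percent of voxels, and unstratified folds can lack positives.
Scaling statistics come from the training folds only. Held-out AUROC and
AUPRC are reported per fold plus their means; AUPRC is interpreted against
the region's base rate (region voxels / mask voxels), the chance level of a
random scorer.

## The phantom

`make_phantom` builds a labeled 3D grid and a matching expression matrix:
disjoint box or ellipsoid regions carry integer labels; each region gets a
disjoint set of marker genes expressed at `marker_amplitude` above baseline
inside the region only (an option shares markers between consecutive
regions, emulating border-defining genes); a `background_fraction` of the
remaining genes is broadly expressed at `background_level` everywhere;
i.i.d. Gaussian noise (`noise_sd`) is added and values are floored at zero,
mirroring nonnegative expression-energy semantics. All draws come from one
`numpy` Generator keyed by the spec seed, so phantoms are byte-identical
across calls. The per-gene z-scoring then runs through the same preprocess
code as real data.

The reference study conditions are eight 10³ boxes tiling a 20³ grid
(labels 2–9), 1000 genes, 30 markers per region (240 markers, 760
broadly-expressed background genes), marker amplitude 1.0, noise SD 0.5,
background level 2.0. Regions tile the grid because reference anatomies
label every in-mask voxel; a labeled background region filling unclaimed
mask voxels is supported (`background_label`) for non-tiling phantoms. The
background level sits at 4 noise SDs so the zero floor is essentially never
hit and the additive-Gaussian noise model is exact; the Gaussian choice
itself is a modeling convenience — the noise structure of smoothed
expression energy is not characterized — and marker amplitude equal to two
noise SDs of raw contrast is a deliberately conservative marker strength.

What the phantom does not emulate: realistic neuroanatomy shapes, spatial
autocorrelation of expression (noise is independent across voxels), slice
artifacts, gene–gene correlation beyond the planted signatures, and
multi-resolution grids. Passing recovery tests therefore show that the
pipeline's machinery is correct and that the methods behave as documented
in a controlled regime; they do not by themselves establish performance on
atlas data.

Problem sizes: sparse-filtering analyses run on the full 8000 × 1000
phantom; the dictionary-learning sweep uses a stride-2 voxel subsample
(1000 × 1000) and the sparse-PCA sweep additionally restricts to 300 genes
(all markers + 60 background), since those estimators cost minutes per fit
at full size without changing the qualitative sparsity trends.

## Degenerate inputs and tie-breaking

Constant features raise in 2-means thresholding and sparsity metrics
(undefined); per-feature failures inside `report` are recorded as missing
values rather than aborting. Dice of two empty sets raises (undefined, not
zero). Feature-to-region Dice ties break toward the smaller region id;
gene-ranking and top-gene ties break by gene id; survivor counts in the
consistency filter round up. Empty co-occurrence (mask too small for the
offsets) raises.
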