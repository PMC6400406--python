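# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quality control

Per-cell metrics are the total UMI count and the fractions of that total
contributed by three curated lists: the 13 mitochondrial protein-coding
genes, a dissociation-stress signature, and hemoglobin (HBB, HBA1, HBA2).
Removal rules use strict inequalities — total < 2,000; mitochondrial
fraction > 0.10 **or** stress fraction > 0.05; hemoglobin fraction > 0.01 —
with exclusive flags assigned in the precedence low_count → stressed →
red_blood_cell, chosen because the count filter is applied first in the
source workflow and RBC removal is described as an additional step.  Each
cell gets exactly one flag, so class counts always sum to the input size
and filtering the retained set again removes nothing.  Fractions use the
cell's unfiltered total as denominator; a zero-total cell has fractions
defined as 0 and is low_count.

## Count smoothing

Each cell's raw profile is replaced by the sum over itself and its k = 10
nearest neighbors.  The neighbor metric is Euclidean distance in the first
10 principal components of median-normalized (each cell scaled to the
median library size), square-root-stabilized counts.  A seeded uniform
jitter of amplitude 0.05 × the per-component coordinate range is added to
the PC coordinates before the neighbor search only — it never touches the
summed profiles; this "dither" breaks ties between near-duplicate cells.
Smoothing is one pass at the final k (a stepwise-doubling variant exists in
the literature; at k = 10 the difference is immaterial and one pass is
simpler to verify).  The summed matrix is rescaled by a single global
factor to the input grand total and converted back to integers by
largest-remainder rounding, so the grand total is conserved *exactly* while
the matrix stays a valid count matrix.

Ten components suffice only when cell-type structure is low-dimensional;
this is an assumption about the data, emulated explicitly by the generator
(below).

## Normalization and transform

Size factors follow the pool-and-deconvolve idea: cells are arranged on a
ring ordered by library size (small/large interleaved so pools mix
depths); for pool sizes {21, 41, 61} (clipped to the cell count) and every
ring start, the pooled profile's median ratio to the average cell yields
one linear equation in the member factors.  The sparse system is solved by
least squares with a weak (w = 0.05) ridge anchoring each factor to its
library-size estimate — this both resolves under-determined systems and
fixes the overall scale — then rescaled to mean 1.  Non-positive solutions
raise, with library-size factors as the suggested fallback.  On pure
depth-scaled data the estimate equals library-size factors exactly.

Normalized expression is Freeman-Tukey transformed, FT(x) = √x + √(x+1),
the classical variance stabilizer for counts; FT(0) = 1.

## Highly variable genes

Per-gene CV² on normalized expression is compared to a technical trend
CV²(μ) = a + b/μ fitted by Tukey-biweight iteratively reweighted least
squares over genes with positive mean (the classical CV²–mean noise model;
a contract-level stand-in for reference implementations of the same idea).
Genes are ranked by observed/fitted CV²; the top ⌈fraction × eligible⌉
(default 5%) are selected after excluding stress-marker and ribosomal
lists.  A minimum-mean filter is exposed (`min_mean`, default 0 — i.e.
none) because both conventions occur in practice.

## Clustering

Cell–cell distance is 1 − Pearson r over the selected HVGs; Ward linkage
gives the dendrogram, cut either at a height or (recommended, since raw
Ward heights are dataset-specific) to a target number of clusters; labels
are renumbered by size.  Cluster merging is first-class: an explicit merge
map is applied verbatim and recorded, and an automatic surrogate
iteratively merges (highest r first) dendrogram-sibling clusters whose
mean literature-marker profiles exceed a correlation threshold — a
reproducible replacement for merges justified by marker similarity plus
map adjacency, which is not a stable criterion.

## Marker selection

For each gene the COI is the cluster with the highest mean expression.
AUROC of the single-gene threshold classifier is computed by the midrank
Mann-Whitney formula, which equals the explicit threshold-sweep ROC area
(asserted against that oracle in the tests, exactly).  The four criteria
use the boundary conventions implied by their wording: AUROC strictly
greater than 0.8 ("exceeding"), detection fraction ≥ 0.80 ("at least"),
COI mean ≥ 1.5 ("minimum"), outside-significant fraction ≤ 0.25 ("at
most").  "Detected" means a nonzero underlying value (on the FT scale,
value > 1); "significantly expressed outside" pools all non-COI cells and
compares against the COI's 25th expression percentile.  Candidates are
ranked per cluster by AUROC, ties broken by detection fraction, then COI
mean, then gene name — a deterministic completion of an unspecified
ordering — and the top 4 are selected.

The proliferation score is the mean across a proliferation-marker list of
gene-wise Z-scores of cluster means; constant genes contribute zero.  It
serves as the package's proliferation readout in place of a trained
cell-cycle classifier, which is out of scope.

The id-score classifier is an L1-penalized multinomial logistic regression
on the 500 most variable training genes (standardized), penalty chosen by
20-fold cross-validated deviance (folds reduced with a warning when a
class is smaller).  A cell's id score is its maximum class probability.

## Integration and label transfer

Batches are merged largest-first in a common PC basis (the pipeline
operates on the first 50 PCs of the HVGs).  Mutual k = 20 nearest-neighbor
pairs between the growing reference and each query batch are found on
batch-mean-centered coordinates, so a bulk shift cannot divert the
matching; of a query cell's pairs only the closest is kept, because the
surplus pairs carry a systematic shortfall along the offset direction and
dilute the correction.  Each query cell is shifted by the Gaussian-kernel
weighted (bandwidth 0.1 × the reference's RMS pairwise distance, in query
space) average of the pair difference vectors; the reference batch is
never moved.  This is a deliberate simplification of the published MNN
method (no cosine normalization, subspace projection, or variance
adjustment) with the same contract: mutual pairs in PC space, reference
fixed, per-cell corrections.  Label transfer is 20-NN majority vote in the
corrected space, ties broken by the smallest mean distance among tied
classes.

## Differential expression

Per gene, a negative-binomial GLM (log link) with design
`~ group + detection_rate` — the detection rate is the centered per-cell
fraction of detected genes, the standard reading of adding a detection
rate to the design — and log size-factor offsets.  Dispersions are
method-of-moments estimates computed within groups (so planted effects do
not inflate them), size-weighted across groups, and shrunk 75% toward a
robust a + b/μ trend over genes; the shrinkage stabilizes small-sample
estimates the way empirical-Bayes trended dispersions do.  The group
effect is tested by a likelihood-ratio test against the detection-rate-only
model (χ², 1 df); this replaces a quasi-likelihood F-test with a same-family
test that is simpler to verify by simulation.  BH adjustment across tested
genes; all-zero genes are skipped and flagged.  The fold-change filter is
strict on both |L2FC| > log2(min_fold) and FDR < max_fdr, with
any-comparison semantics across multiple contrasts.

## Pseudotime

The principal tree is seeded k-means (default n_nodes = max(10,
⌈n_cells/100⌉)) joined by a Euclidean MST; leaf arms with fewer than 2
nodes — single stray nodes hanging off a junction, a characteristic
artifact of centroid MSTs — are pruned before use.  Cells project to the
nearest point on any edge; pseudotime is geodesic arc length from the root
(a node, or the node nearest a named cluster's centroid, e.g. the
pretubular aggregate) to the projection; branch ids are the maximal
segments between branch points and leaves.  This replaces reversed-graph
embedding (DDRTree/Monocle 2) deliberately: same contract — tree, rooting,
geodesic pseudotime, branch assignment — at a fraction of the complexity,
so trajectory figures are reproduced in spirit, not numerically.
Trajectory embeddings use 2–3 principal components, matching how such
embeddings are run in practice.

## Enrichment

One-sided (greater) Fisher's exact test: p = P(X ≥ overlap) under the
hypergeometric law of the 2×2 table; odds ratio reported, ∞ flagged when a
margin cell is zero.  The universe defaults to all genes detected in the
expression matrix (the choice is configurable since published universes
are often unstated).  BH adjustment is the step-up formula, capped at 1.
The kidney- and lung-trait GWAS lists are registry entries supplied by the
user; catalog retrieval is out of scope because catalog versions drift.

## Imaging

Rolling-ball background subtraction is implemented as grayscale opening
with a disk (the standard surrogate; radius 3 px for smFISH, 100 px for
immunostains).  Autofluorescence removal regresses each channel on the GFP
channel over ROI background pixels (below the channel's Otsu threshold)
*with an intercept*, so a flat noise floor is not absorbed into the scale,
and subtracts only the scaled GFP component.  Spot calling binarizes at a
global threshold — Otsu within the ROI by default, or an absolute value,
which is the robust choice for sparse fields where Otsu's two-class
assumption fails — labels 8-connected components, and retains those with
mean intensity strictly above the ROI's third quartile (computed over all
ROI pixels) and area ≥ 3 px.  Density is count / ROI area, converted to
μm⁻² via `pixel_size` only at reporting.  Group densities are compared by
two-sided Mann-Whitney tests with BH adjustment (the conservative default
for a small-sample comparison) and stars at adjusted p < 0.05 / < 0.0005.

Niche profiles: cross-sections are either hand-drawn polylines or
auto-generated normals to the ureteric-bud contour every 30 px of arc
length, oriented into the tissue mask.  Intensity is sampled at 1-px steps
in distance d, each step averaged over a perpendicular line of 30 px
(bilinear interpolation), masked to the ROI.  A section's s value is its
origin's arc length over the total contour length.  The d-profile averages
sections per 1-px bin; the s-profile averages each section over d and bins
s.  Profiles are max-normalized; SEM is over contributing sections.  The
ratio profile divides the first channel's normalized d-profile by the
second's (the pre-normalization ratio is retained alongside).  All
geometry is pixel-center, 0-based, (row, col).

## Synthetic data: what it emulates, and what it does not

`generate_counts` draws NB counts (variance = μ + φμ², the Bioconductor
convention; φ → 0 is the Poisson limit) with: lognormal gene abundances
(σ = 0.6) and per-cell depths (σ = 0.25); 22 cell types × 150 cells and
2,000 genes by default, giving ≈5,000 expected UMI per cell — the scale of
a mid-gestation kidney sample (reported median ≈4,800); 4 exclusive
markers per cluster at fold 8, exact in expectation because rows are
normalized by the common baseline; low-rank cluster "programs" (8 latent
factors, per-gene log-sd 0.5) so cell types occupy a low-dimensional
manifold — the structure 10-PC smoothing assumes and real tissue exhibits;
and designated stressed/RBC/low-count subsets whose planted mitochondrial
/ stress / hemoglobin fractions sit at twice the removal thresholds
(0.20/0.10/0.02), implemented by reallocating the cell's expected total,
so thresholds are exceeded in expectation rather than deterministically.
Curated-list genes get a lower dispersion (0.02) than the gene baseline
(0.1), reflecting the decreasing mean–dispersion trend of real data; with
the baseline dispersion a 2× margin would not support near-perfect recall,
which real stressed/RBC populations (whose fractions sit far above
threshold) do exhibit.  QC-failing subsets default to zero cells and are
enabled explicitly by QC-focused analyses.

`generate_trajectory_counts` lays segments of a tree topology on a latent
time axis; dynamic genes interpolate seeded log-fold endpoints per segment
(continuous at branch points), ten monotone genes rise log-linearly over
the span, and each segment owns a marker program (4 genes, fold 8) that
ramps up within the segment and stays on in descendants — fate identity
accumulates, consistent with the cluster generator's marker strength and
with terminal fates being distinct cell types.

`generate_spot_image` / `generate_gradient_image` compose background,
optional autofluorescence, Gaussian spots (σ = 1.2 px, diffraction-limited
scale), an exponential gradient exp(−d/λ) off a contour polyline, and
Gaussian noise, in 2-D (stacks are max-projected upstream in the real
workflow).

Not emulated: ambient RNA, doublets, batch-specific library chemistry,
cell-cycle structure beyond a single proliferative cluster flag, 3-D PSFs,
and spatial autocorrelation of camera noise.  Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
generative assumptions, not robustness to every artifact of real data.

## Problem sizes and seeds

Tests and the acceptance script run at desk scale: the marker-selection
analysis uses the full default fixture (22 × 150 cells, 2,000 genes); DE
calibration uses 2,000 genes × 100 + 100 cells; trajectory recovery uses
450–600 cells; images are 256². Sizes were chosen so each check runs in
seconds to a couple of minutes while keeping estimator noise well inside
the asserted margins.  Every stochastic component takes an explicit seed;
identical seeds give bit-identical results.

## Known limitations

- The pool-deconvolution solver anchors to library-size factors with a
  weak ridge; under extreme composition bias the anchor can pull factors
  slightly toward library size.
- The MNN stand-in corrects shifts well but, with a single pass and
  best-pair selection, residual distortion remains for batch effects that
  are not locally constant; `n_iter` > 1 re-pairs on corrected data.
- The NB LRT is asymptotic; at very small group sizes (< ~20 cells) its
  type-I error is not guaranteed by the calibration checks performed here.
- Centroid-MST pseudotime has no uncertainty quantification and assumes
  the trajectory is tree-shaped in the embedding used.
- Otsu thresholding for spot calling assumes a bimodal intensity
  histogram; sparse fields should use an absolute threshold.
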