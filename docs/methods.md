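# Methods

This note documents the models, algorithms and numerical choices behind
`somportrait`, the assumptions they rest on, and what the synthetic-cohort
experiments do and do not demonstrate.

## Preprocessing

Input is a genes × samples matrix on log2 scale (a `log2(x+1)` transform
is available for raw intensities). Quantile normalization forces every
sample column onto the across-sample mean of the order statistics; ties
within a column receive the mean of the order-statistic means their rank
range spans, which makes the operation deterministic and equivariant
under sample permutation. Gene centering subtracts each gene's row mean
(mean, not median — the convention of the SOM-portrayal literature), so a
portrait value is a log fold change against the cohort average. Upstream
concerns of real array data — probe summarization, batch correction,
outlier and missing-value handling — are assumed solved before input;
the readers reject missing expression values explicitly.

## Batch SOM of gene profiles

Data points are gene profiles (dimension = number of samples), not
samples: the map summarizes the gene space, and samples are read off as
codebook columns. Training is batch mode, which makes the result
independent of gene order up to floating-point summation and
reproducible from a seed:

* **Initialization** — the codebook spans ±2 SD of the first two
  principal components of the gene profiles (SVD with a deterministic
  sign convention); seeded random jitter is the fallback for degenerate
  covariance. PCA initialization keeps the global orientation of the map
  stable across seeds; remaining seed effects enter through K-means
  restarts downstream, not the SOM.
* **Epochs and radius** — 20 epochs; the Gaussian neighborhood radius
  decays linearly from `max(rows, cols)/2` to 0.5. The wide early radius
  unfolds the map globally (quantization error transiently rises above
  the PCA start in epoch one, then decreases monotonically); the final
  radius of 0.5 keeps enough neighborhood coupling for a smooth map while
  letting a cluster of co-expressed genes occupy an area roughly
  proportional to its size. A final radius near 1 over-smooths: planted
  modules collapse onto one or two units and can no longer be segmented.
* **Ties and empty units** — equidistant BMUs resolve to the lowest unit
  index; units whose neighborhood-weighted denominator vanishes keep
  their previous codebook vector (dense-map style, no pruning).
* **Grid size** — a free parameter. Population-scale maps use 100×100;
  all shipped defaults and tests use 16×16, which is the smallest grid at
  which thirteen modules plus their separating halos fit comfortably at
  2,000 genes. Quantization error is reported per epoch as a diagnostic.

## Spot segmentation

The over-expression summary is the per-unit 98th percentile of codebook
values across samples — a robust "maximum expression" map that flags
units strongly over-expressed in at least ~2% of the cohort. Candidate
units are those whose summary exceeds the 97.5% quantile of *all*
codebook expression values. Thresholding on the pooled expression
distribution rather than on the summary map's own quantiles makes the
criterion an expression level, independent of how much grid area the
modules occupy, and therefore transferable across grid sizes.

The U-matrix (mean Euclidean distance of each unit's codebook vector to
its 8 neighbors) supplies the segmentation barriers: candidate units
above the 60% U-quantile *of the candidate set* are masked out before
8-connected component labeling, then re-attached to a component when all
their labeled neighbors agree. Candidate clusters consisting entirely of
halo units (small isolated blobs have no low-U core) are promoted to
components of their own; genuine bridges between two spots stay small and
are removed by the `min_units = 4` filter. Components are capped at
`max_spots = 25` and labeled A, B, C, … by decreasing gene count — the
letters are map-specific and carry no meaning across runs.
Under-expression spots can be segmented symmetrically on the mirrored
codebook (`direction="under"`) but are disabled by default.

Spot-to-spot association uses Pearson correlation of the per-sample spot
profiles (signed edges at |r| ≥ 0.5). Zero-variance profiles never
connect.

## Stratification

A sample over-expresses a spot when its spot expression, standardized
across the cohort (population SD), exceeds `z_threshold = 1`. The
resulting combinatorial patterns (cPATs) are counted exactly; patterns
with ≥ 5 samples are flagged "major" in the enumeration, while the type-
count estimator uses a stricter 15-sample cutoff at the default cohort
size — patterns that barely clear five samples are noise-contaminated
variants whose centroids destabilize the dendrogram. The estimator
average-links the major-pattern centroid portraits and cuts at the
largest gap between consecutive merge heights (the gap from zero to the
first merge is excluded: it dominates whenever centroids carry any noise
and would always return one cluster per pattern), bounded to [2, number
of major patterns].

K-means (k-means++, 25 seeded restarts) on the full metagene portraits
assigns types; a second K-means within each type yields subtypes.
Cluster ids are renamed deterministically: clusters are ordered by the
mean of a reference score (a supplied per-sample reference profile such
as a lymphocyte-associated spot, or by default the portrait dimension of
highest variance), and with three clusters the one whose centroid has the
weakest mean |correlation| to the two poles is named "M". Validation is
10 rounds of 70/30 stratified holdout with a shrinkage linear
discriminant (`lsqr`, automatic shrinkage) — a regularized linear
classifier appropriate when the portrait dimension exceeds the training
count; rounds missing a class are skipped with a warning.

## Function mining

Fisher overrepresentation is the exact hypergeometric upper tail
`P(X ≥ overlap)` (so zero overlap gives p = 1), with Benjamini–Hochberg
FDR across all (spot, set) pairs. The GSZ sample score standardizes the
set-vs-universe mean contrast by an equally weighted pool of the set and
universe population variances; the pooling weight is exposed, a singleton
set falls back to the universe variance, and a vanishing denominator
returns 0. Population (n) variances keep the toy examples exactly
reproducible. GSZ is invariant under adding a constant to a sample's
expression and under rescaling it. Gene-set maps count set genes per
unit via their BMUs; counts are conserved.

## Phenotype portrayal

Continuous features correlate with each metagene by Pearson; binary
features by point-biserial correlation, computed as Pearson on the 0/1
coding (a mathematical identity, asserted to machine precision in the
tests); categorical features expand one-vs-rest. Missing values are
dropped pairwise and the number used is reported per map; zero-variance
features are rejected, zero-variance units get r = 0. Type enrichment of
categorical levels is a right-tailed hypergeometric test per (type,
level) cell with BH-FDR across cells and an enriched/depleted direction
flag. Spot regression z-scores response and predictors and fits OLS;
collinear predictor columns are dropped (later columns first) with a
warning and reported. LOESS is degree-1 tricube local regression
(span 0.5 default, robustness iterations 2) evaluated on a 100-point
even grid by interpolating the fitted values; spans leaving fewer than
four local points are widened with a warning.

## The synthetic cohort

The generator emulates the statistical skeleton of a population blood
cohort at desk scale — 2,000 genes × 300 samples by default; dimensions
scale freely. Non-background genes partition into 13 modules of 100
genes (35% background): spots in real cohort maps tile most of the grid,
and leaving three quarters of genes unstructured would starve the modules
of map area. Activations in log2 units:

* **Types** — two pole types and one intermediate type. A module sits at
  baseline 0 in its own type, −3 in the opposite pole and −1.5 in
  intermediate pairings (graded suppression), which yields anti-correlated
  pole portraits with a genuinely intermediate group between them.
* **Subtypes** — within each type, modules are boosted +5 in a singleton
  or a two-subtype combination, so each of the nine subtypes
  over-expresses a unique module combination (the cPAT ground truth) and
  every module has a distinct activation profile.
* **Independent module** — one module is uncoupled from the types and
  jumps +8 in a random 10% of samples, emulating a type-independent
  interferon-response program; +8 keeps its mean-centered over-expression
  footprint comparable to the suppressed-and-boosted type modules under a
  single expression threshold.
* **Module activity variability** — every (sample, module) pair receives
  i.i.d. N(0, 1.5²) activity noise. Real module activity fluctuates
  between individuals beyond the stratum structure; numerically this
  decorrelates module profiles so the map separates them, while leaving
  the type signal dominant for clustering. (Raising it to ≥ 2.5 makes
  spots trivially separable but destroys cPAT purity and typing.)
* **Phenotypes** — age ~ U(40, 80); sex ~ Bernoulli with ±0.8 log-odds
  skew toward the poles (sex = 1 enriched in pole "2"); BMI ~ N(27, 4²)
  clipped to [16, 45]; a disease flag with logistic dependence on age and
  ±1.0 log-odds pole skew. Couplings add β · z(phenotype) to module
  activations (age → the first pole's two-subtype module, β = 1; BMI →
  that pole's first singleton module, β = 0.8; disease → its second
  singleton module, β = 1; sex → the opposite pole's two-subtype module,
  β = 0.8). Effect sizes are stated in log2 units per phenotype SD; the
  type skews mirror the demographic asymmetry of real cohorts (one pole
  over-representing men, the elderly and disease history).
* **Noise** — gene-level residuals are i.i.d. N(0, 1).

What passing tests show: the pipeline recovers planted module count and
membership, type and subtype partitions, and phenotype couplings under
Gaussian noise with exactly known structure. What they do not show:
robustness to probe-level artifacts, batch effects, non-Gaussian
heavy-tailed biological variation, correlated background genes, or
modules with graded (non-binary) gene loadings — the generator plants
none of these.

## Reference problem sizes

All shipped defaults, the test suite and the acceptance script use the
2,000 × 300 cohort with a 16×16 map, which one pipeline run completes in
a few seconds; recovery quantities are medians over five replicate
cohorts. Across ten replicate cohorts the recovered spot count has
median 13 with occasional ±2–3 excursions (splits and merges of adjacent
same-type blobs); the estimated type count is 3 in nine of ten
replicates; type ARI is ≥ 0.97 in nine of ten, and held-out
misclassification stays ≤ 2%.

## Known limitations

* The merge-height-gap estimator for the type count is the fragile step:
  on roughly one replicate in ten it returns 2 or 4 when the pattern
  centroids blur, dragging type ARI down for that replicate. The medians
  are stable.
* Spot letters are size-ordered and not comparable across maps or seeds.
* The U-matrix barrier segmentation cannot split two modules whose
  activation profiles are nearly identical — by construction such
  modules are one co-expression unit.
* cPAT purity degrades gracefully with module-activity noise: individual
  samples pick up false spot calls at z = 1 (~5% per spot), so exact
  pattern matching holds for the modal pattern per subtype, not for every
  sample.
* The spot correlation network uses Pearson correlation of spot profiles;
  overlap-weighted association measures from the wider literature are out
  of scope.
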