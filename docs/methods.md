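# Methods

This note records the statistical models behind `insituprox`, the
parameters that matter, what the synthetic-tissue generator does and does
not emulate, and the design decisions taken where more than one
construction was defensible.

## Data model and distances

A tissue sample is a per-molecule transcript table (gene, 3D position in
pre-expansion µm, owning cell, field of view, optional
nuclear/cytoplasmic compartment, bacterial flag) plus the derived
cell-by-gene count matrix. Raw coordinates are divided by the expansion
factor at ingest, so everything downstream works in pre-expansion µm.
Cells with fewer than 50 detected molecules are dropped at ingest
(configurable); this quality filter is applied globally, not only before
cell typing. Bacterial (16S-barcode) reads never enter host counts.

Two distance conventions exist. *Boundary* distance is the minimal 3D
Euclidean distance over all transcript pairs of two cells — the natural
convention when molecule clouds delineate cell extent. *Centroid*
distance is used for lower-resolution platforms and is capped at 145 µm
(≈ the diagonal of a 100 µm field of view, so both conventions see a
comparable search range). All thresholds are inclusive (≤). Distance-
response analyses on boundary-convention data are scoped to the cell's
field of view; all other analyses search the whole tissue. Cells whose
molecules straddle an FOV border belong to the FOV holding the majority
of their molecules. Distances are computed in full 3D; for thin sections
the z-contribution is small but never ignored.

Proximity ("contact") means boundary distance ≤ 1 µm to any cell of the
target type. A type pair in a tissue is analyzable when it has at least
one proximal and one distant cell and at least 3 cells in total (the
minimum for a 2-component embedding).

## Shared permutation machinery

All permutation tests fit a normal distribution to the permuted
statistics and read the observed statistic's one-sided tail off that fit
(`stats.normal_approx_p`). Degenerate nulls (sd = 0) return 0.5 on a tie
and 0/1 otherwise, with a warning. Benjamini–Hochberg adjustment is the
step-up rule; the test suite checks it against both the brute-force
definition and `statsmodels`. Binomial tails are exact (regularised
incomplete beta), which keeps values around 1e-73 meaningful.

## Proximity dispersion

For each (tissue, type-i, type-ii): the type-i count matrix is z-scored
per gene (genes undetected in the type are dropped), embedded by PCA, and
the PC1–PC2 scores carry two statistics — the summed distance of proximal
cells from the centroid of *all* type-i cells, and the distance between
the proximal and distant centroids. Both are z-scored against a
label-shuffling null (10 000 shuffles by default) that preserves the
proximal subset size, and combined as Z_max = max of the two z-scores
(the two measures are strongly correlated; testing their max avoids
double counting). **Null of the max**: within each permutation both
statistics are z-scored against the full permuted distributions and their
max taken; the observed Z_max is referred to the upper normal tail of
that per-permutation max distribution. The proximity contribution to
variance is proximal dispersion / total dispersion; under exchangeability
its expectation is the proximal cell share. PCA sign is fixed by making
each component's largest-magnitude loading positive, so embeddings are
reproducible. A sensitivity mode re-runs the test after dropping the
neighbouring type's marker genes (segmentation-artefact guard).

## Negative-binomial DE engine

One engine serves proximity, triplet and bacteria contrasts:
median-of-ratios size factors (geometric-mean reference over genes with
all-positive counts; total-count fallback otherwise); per-gene
method-of-moments dispersions computed *within* the two condition groups
and pooled (so a true condition effect does not inflate the dispersion),
shrunk 50/50 in log space toward a fitted a₀ + a₁/µ trend; and a Wald
test on the two-group contrast of a log-link NB model. Because the design
is one two-level factor, each group's coefficient solves a 1-D score
equation, handled by a vectorised Newton iteration — this is what makes
the 1000-fold label-permutation wrapper affordable (size factors and
dispersions are frozen across permutations; only the Wald statistic is
recomputed). The permutation p is add-one smoothed on the absolute Wald
statistic. A reported ("significant") gene must clear the BH-adjusted
nominal test (q < 0.05), the uncorrected permutation check (p_perm <
0.05; its resolution is 1/(n_perm+1), so a BH-corrected permutation
q cannot reach 0.05 for a lone discovery at practical n_perm — both
corrected columns are still emitted), and a fold-change filter
(|log2FC| ≥ 1 by default; the threshold is configurable as no canonical
value exists). Independent filtering and outlier-replacement refinements
of reference bulk implementations are deliberately omitted; the
permutation layer is the robustness mechanism here.

Triplet contrasts pool cells across samples: condition 1 = focal cells
proximal to ≥1 B and no C; condition 2 = proximal to ≥1 B and ≥1 C; both
conditions need ≥ 5 cells. Bacteria contrasts ('include' vs 'distant')
should be run within one cell type — across types, composition imbalance
between the small include group and the rest masquerades as differential
expression of type markers.

## Program concordance

Per-tissue DE p-values for one cell-type pair are intersected to genes
expressed in every tissue (total count > 0 in the relevant type), exact
zeros are replaced by 0.8 × the global minimum nonzero p, −log10
transformed and z-scored per gene across tissues. Explained-variance
significance per PC and the paired/grouped PC1–PC2 distance tests share
one null: shuffle each gene independently across tissues, re-standardise,
re-project, and (for distance tests) affinely rescale each permuted PC
axis so its [min, max] maps onto the observed axis's [min, max] —
anchoring at the extremes is the simplest affine map that makes distances
numerically comparable across permutations. Distance statistics use the
lower tail (closer than chance).

## Spatial RNA velocity

Nuclear counts proxy unspliced u, cytoplasmic counts spliced s.
Cytoplasmic depth normalisation multiplies each cell by (global mean
total)/(cell total). Counts are smoothed over each cell and its K = 30
nearest neighbours in the first three PCs of the normalised cytoplasmic
matrix. γ per gene is the least-squares slope of u on s **through the
origin**, fitted on cells in the top and bottom 7.5% of total (u+s)
expression — extreme-expression cells hug the steady-state line while
intermediate cells form the off-line lobe. The regression direction
follows from the velocity equation v = u − γs (γ carries units of u per
s); fitting s on u instead would estimate 1/γ. Reliability: a gene's γ is
trusted when its maximum within-cell expression fraction (count / cell
compartment total, over both compartments) reaches 0.038 — the published
F-score-optimal threshold; the fraction scale is the one normalisation
under which that cutoff is dimensionless. Future states S(T) = S(0) + vT
(T = 3) are floored at 0; cells whose total future expression drifts
> 10% are counted and the run aborts only if every cell violates the
bound. Both matrices are scaled by their mean totals; PCA axes are fitted
on the **current** normalised states and future states are projected into
those fixed axes (axis stability; joint fitting is a config choice).
Magnitude of change = PC1–PC2 displacement length, current magnitude =
distance from the origin, phase = displacement angle in (−π, π].
Magnitudes are tested against distance-shuffling nulls (two-sided);
phase uses a circular–linear correlation with the same null (upper tail).

A caveat worth knowing: when a sizeable subpopulation violates steady
state (strong induction), its cells contaminate the extreme-quantile γ
fit and the mean-total scaling of S(T); the *current*-state magnitude
remains a faithful proximity readout while the future-state magnitude can
change sign. The synthetic recovery test therefore anchors on the
current-state correlation.

## Distance response

Per (tissue, X, Y): X cells with a valid minimal distance to Y (same-FOV
boundary, or capped centroid) are regressed gene by gene — raw counts on
distance. Raw counts (not normalised values) are the regression units
because the retention filters are count-based; a normalised mode is a
config option. Genes are retained only if they fail **both** exclusion
rules: 98th-percentile expression ≤ 10 counts, or detection in ≤ 20
cells. Outputs per gene: slope, intercept, R², the mean R² over 100
distance-shuffles (≈ 1/(n−1) under independence), the coefficient t-test
p (identical to default OLS in statsmodels, verified in the suite),
q from one global BH family over all gene × pair × tissue tests, and the
98th percentiles of expression and distance. Significant genes (q < 0.05)
then pass a robustness filter: sort cells by distance, Gaussian-smooth
the expression vector with σ = 5 **in sorted-rank units** (the smoothing
is defined on the ordering, not the distance scale), re-regress, and drop
genes with smoothed R² < 0.5 (0.3 available for centroid-convention
platforms). Survivors are ranked by a composite score: eight features
(|slope|, R², Gaussian R², n cells, p98 expression, p98 distance —
larger better; mean permuted R², q — smaller better), each ranked with
average ties, reversed (n − rank) and summed.

## Neighbour response

Neighbour counts (cells of type Y within 15 µm boundary distance; 10 and
20 µm for robustness; 40 µm centroid for Xenium-style data; self excluded
when Y = X) are heavily zero-inflated, which drags a plain OLS toward the
crowded low-count bins. Exact integer counts form bins; bins with < 10
cells are dropped and a pair needs ≥ 4 surviving bins. Genes with zero
expression are removed, then the top 20% most variable retained. The
primary estimator draws 10 cells from every valid bin, fits OLS, repeats
1000 times; the slope is the mean of iteration slopes and the intercept
is refit to the original data (ȳ − b·x̄). Significance is the median of
the per-iteration coefficient p-values — a deliberately conservative
aggregation chosen because the iterations are resamples of the same
data, so pooling them as independent would overstate evidence; the
standard-OLS p is retained in the output for audit. Cross-check
estimators: WLS with inverse bin-frequency weights (raw and
sum-normalised weights are algebraically identical — the suite asserts
it), and line aggregation (evaluate all 1000 iteration lines on the
observed count grid, pool, refit; on a common grid this returns exactly
the mean iteration slope). The consensus set intersects significant
genes across all methods and cutoffs, with an optional matched-reference
detection filter (≥ 10% of reference cells).

## Microbial objects

16S read positions are clustered by DBSCAN (min_samples = 3, the
neighbourhood count including the point itself — held fixed and matched
by the brute-force oracle in the suite) over a radius grid; the sweep
default is 1–150 in the stored coordinate units, and because the
pixel↔µm conversion of any particular acquisition is instrument-specific
the grid should be rescaled via configuration when coordinates are not
µm. Each cluster's compactness (sum of pairwise member distances) is
referred to the lower normal tail of equal-size random draws from the
most frequent host gene's transcripts in the same FOV (whole tissue when
the FOV reference is smaller than the cluster). Precision = significant
clusters / clusters; recall = clustered reads / all bacterial reads; the
F1-maximising radius wins, ties to the smallest. Host cells are classed
'include' (≥ 1 significant bacterial read within the cell's transcript
envelope — the 95th percentile of its own molecules' distance to
centroid), 'proximal' (none inside, one within 1 µm of any of its
molecules) or 'distant'; only significant objects' reads count.

## Cell typing

Markers come from matched single-cell DE tables filtered at average
log2FC > 5 and adjusted p ≤ 1e-200 (the operational meaning of "adjusted
p of zero"); a gene marking several types survives only for the sole type
reaching p ≈ 0, otherwise it is dropped; canonical markers join by
union. Clustering runs over a grid of (number of PCs ∈ {6..30 step 2},
resolution ∈ {0.2..2.0 step 0.2}; ~130 combinations): per-cell depth
normalisation to 1e4, log1p, per-gene scaling (clipped at 10), PCA, a
15-NN graph and Leiden modularity communities (RB-configuration
objective; the backend is pluggable behind the labels-from-counts
contract). Cluster → type assignment uses one-vs-rest Wilcoxon rank-sum
q-values of marker genes on depth-normalised counts (rank-sum is robust
for sparse targeted panels): a sole supporting marker with q ≤ 1e-9
assigns; same-type multiples assign on the best q; different-type
competitors assign only when exactly one reaches q ≈ 0 or the leader
dominates (log10(q1/q2) < 0.3·log10(q2) and q1 ≤ 1e-9); double q ≈ 0
leaves the cluster unassigned. Solutions with more than three inferred
types vote; a cell's modal label needs ≥ 20% of retained solutions *and*
≥ 10 solutions (both thresholds are sized for the full grid and are
parameters — reduced grids should scale them). Validation shuffles every
gene's counts across cells (per-gene multisets preserved), reruns the
whole pipeline 20 times, and tests the observed number of labelled cells
against the shuffled null (upper tail).

## Synthetic tissues

The generator emulates: a targeted panel (299 genes by default) with a
lognormal expression backbone and a few boosted marker genes per type;
five cell types at realistic proportions; ~170 molecules per cell with
lognormal cell-to-cell depth (σ = 0.25); negative-binomial counts
(dispersion 0.3); Gaussian molecule clouds (sd = cell radius, 3 µm)
around uniformly placed cell centres in a 300 × 300 × 30 µm slab tiled
into 100 µm FOVs — a packing density at which roughly a quarter of cells
have a ≤ 1 µm contact, matching the regime the analyses target.

Planting is two-pass: background genes are drawn and placed first, the
spatial covariates (stratifications, minimal distances, neighbour
counts, triplet conditions) are measured on those molecules **through
the same code paths the analysis uses**, and only then are planted-gene
counts drawn from covariate-dependent means (proximity shift: +Δ·sd on
the NB scale; distance/neighbour: mean = max(0, a + b·covariate);
triplet/bacteria: multiplicative). Planted molecules are placed at half
the cloud spread — molecules near the centre never set boundary minima,
so planting does not disturb the geometry it conditioned on. Effects may
pin a gene's baseline mean. Velocity tissues draw u ~ Poisson(γ·s)
(steady state) with optional induction (u inflated) by type or by a
proximity rule; rule-induced cells also shift part of their cytoplasmic
profile, because an induced cell is in a different *state* — without
that, expression-space KNN smoothing correctly averages induced and
uninduced neighbours and no method could (or should) recover the signal.
Bacterial clusters are Gaussian point clouds centred on host cells
(optionally of one type) plus uniform noise.

Not emulated: tissue morphology, segmentation errors, spatial
autocorrelation of expression beyond the planted effects, doublets,
platform-specific noise. Passing tests therefore certify the statistics
and their calibration, not robustness to segmentation artefacts.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale as the
package's own verification design: tissues of 90–600 cells, panels of
20–150 genes, permutation counts of 100–2000, calibration at 500
replicates × 500 permutations, slope-recovery tissues of 1500 cells.
Random streams for data generation and for permutation machinery are
always derived separately from the master seed — sharing one stream
couples the data to its own null and biases calibration (this was
observed and is guarded by the calibration suite). End-to-end
verification runs each module on its own tissue carrying exactly one
planted effect; false positives are counted on outputs with no planted
signal (for the dispersion module, on pairs whose primary type carries
no planted program, since a planted state in type i legitimately flags
every (i, ·) pair).

Known limitations: the NB Wald test is slightly conservative at very
small group sizes; the iterative-sampling p does not sharpen with more
cells per bin (its per-iteration sample is fixed by design); the
future-state magnitude inherits the γ-contamination caveat above; exact
permutation enumeration is out of scope.
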