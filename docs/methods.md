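# Methods

This note documents the models implemented in `wm_morphnet`, the defaults
that matter, the synthetic data the tests rely on, and the numerical choices
made where the design was genuinely open.

## Network construction

**Regional densities.** Voxel values of each atlas region are smoothed into
a probability density by a Gaussian KDE with Silverman's rule-of-thumb
bandwidth, bw = σ̂·(3n/4)^(−1/5) (σ̂ the sample SD, ddof = 1), evaluated at
`n_points` equally spaced grid points over [min − 3·bw, max + 3·bw] and
normalized to unit mass. The default `n_points = 256` (2⁸); the
`frechet_diagnostic` utility quantifies how much the density curve still
moves between adjacent powers of two (discrete Fréchet distance), which is
the standard way to confirm that 2⁸ points are enough for a given dataset.
Regions with fewer than two in-mask voxels or constant values raise an
error naming the offending region IDs rather than silently producing a
point mass.

**Pair alignment.** The Jensen–Shannon sums require both PDs on one grid.
For every region pair, both densities are re-evaluated on a shared
`n_points` grid spanning the union of the two regions' [min − 3·bw,
max + 3·bw] ranges. Region-specific grids would make Σ Pᵢ log(Pᵢ/Mᵢ)
ill-defined; the union grid is the smallest support that loses neither
tail.

**Similarity.** JSDs = 1 − JSD with base-2 logarithms, so both quantities
live in [0, 1] and JSDs = 1 exactly when the PDs coincide. Terms with
Pᵢ = 0 contribute exactly zero (0·log 0 ≡ 0); Mᵢ = 0 with Pᵢ > 0 cannot
occur since M = (P+Q)/2 ≥ P/2. Some earlier morphological-network work uses
1 − √JSD instead; this package implements the plain complement and leaves a
root transform to the caller (`1 - (1 - jsds)**0.5` if wanted).

**Smoothing.** Optional isotropic Gaussian smoothing with FWHM in mm
(default 8 mm when used), σ = FWHM/(2√(2 ln 2)) per axis converted to
voxels. Boundary handling is constant-zero padding — the common
neuroimaging convention — so mass is conserved for interior signal but not
for signal within a kernel radius of the volume edge.

## Topology

**Thresholding.** A similarity network is binarized at a target sparsity S
(fraction of the R(R−1)/2 possible edges). The maximum spanning tree of
similarity is kept first — this is the "minimum spanning tree" guarantee on
a similarity (not cost) matrix, equivalently the MST of 1 − similarity —
then the strongest remaining edges fill up to round(S·R(R−1)/2). Ties break
deterministically by similarity descending, then region-index pair
ascending. The default sparsity grid is [0.09, 0.30] in steps of 0.02
(11 levels), a range that keeps networks sparse but estimable for
small-world attributes.

**Null models.** Small-world normalization (γ = Cp/⟨Cp_rand⟩,
λ = Lp/⟨Lp_rand⟩) and rich-club normalization use the same family of
degree-preserving rewired graphs: 10·E attempted connected double-edge
swaps per null (configurable), 100 nulls by default. Each swap preserves
every node's degree exactly and connectivity is maintained throughout.
Graphs too rigid to admit any swap (e.g., a triangle) serve as their own
null, giving γ = λ = 1.

**Degree models.** The complementary cumulative distribution of mean nodal
degree (averaged across subjects and sparsity levels) is fitted by
nonlinear least squares under three forms — c·k^(−a) (power law),
c·e^(−k/kc) (exponential), c·k^(a−1)·e^(−k/kc) (truncated power law) — and
the best model minimizes AIC = n·log(RSS/n) + 2·(number of parameters).
RSS is floored at 1e−12 so that nested models which both fit to solver
tolerance are separated by the parameter-count penalty rather than by
floating-point noise. Hubs are regions with z-scored mean degree strictly
greater than 1 (SD with ddof = 1).

## Reliability and heritability

**ICC.** One-way random-effects ANOVA per edge on a balanced
subjects × sessions panel: ICC = (MS_b − MS_w)/(MS_b + (k−1)·MS_w).
Negative estimates are reported as-is and classified "poor"; the category
bands are poor < 0.25 ≤ low < 0.4 ≤ fair < 0.6 ≤ good < 0.75 ≤ excellent.

**ACE.** Per edge, intrapair Pearson correlations r_MZ and r_DZ give the
Falconer method-of-moments components A = 2(r_MZ − r_DZ), C = 2r_DZ − r_MZ,
E = 1 − r_MZ, projected onto the nonnegative orthant before
h² = A/(A+C+E), so h² ∈ [0, 1]. This transparent estimator was chosen over
a likelihood-based variance-component fit for desk-scale testability; a
maximum-likelihood estimator is a documented extension point.
Significance permutes the MZ/DZ labels across pairs (pairs stay intact)
with the add-one rule. The permutation statistic is the *unprojected*
additive estimate 2(r_MZ − r_DZ): the projected h² has a point mass at 0
under the null (about half of null edges), which would make p-values pile
up near 1 instead of being uniform; the unprojected statistic is
continuous and order-equivalent to h² wherever h² > 0, so the test is
calibrated without changing what is reported. BH-FDR at q = 0.05 across
edges.

## Communication model

Shortest path length (hop count) and communicability (exp(A), the
walk-weighted sum) are computed on individual binary networks and averaged
across subjects and the default sparsity grid — the sparsity at which the
original communication measures were taken is not fixed by any convention,
so averaging over the same grid as the topology battery is this package's
documented choice. A target network is regressed edge-wise on
[morphological similarity, shortest path, communicability]: whole-brain on
the R(R−1)/2 unique edges, node-wise on each node's R−1 profile;
performance is adjusted R² with p = 3 predictors. Significance regenerates
the *target* from Moran surrogates (not the predictors), one-tailed with
the add-one rule, BH-FDR across nodes. Because Moran surrogates are defined
for regional maps, a surrogate of a symmetric target matrix is produced by
randomizing each region's connectivity profile on the shared Moran
eigenbasis and symmetrizing ((S + Sᵀ)/2, diagonal preserved) — a package
choice, documented here because no standard exists for matrix-valued maps.

**Gradients.** Connectivity gradients use the standard diffusion-map
embedding: each row of the (nonnegative) network keeps its top 10% of
entries, the affinity is the cosine similarity between thresholded rows,
the affinity is normalized with anisotropic diffusion α = 0.5, and the
embedding uses automatic diffusion time (eigenvalue scaling λ/(1−λ)).
Explained-variance fractions are the normalized nontrivial eigenvalues. A
row-thresholded affinity that falls apart into disconnected components is
rejected with a clear error (the embedding is undefined there) rather than
returning numerically exploded coordinates.

## Surrogates and group inference

**Moran spectral randomization.** Spatial weights default to inverse
Euclidean distance between region centroids (zero diagonal). The map is
decomposed on the orthonormal eigenvectors of the doubly centered weight
matrix (the Moran eigenvector maps, spanning the centered subspace);
surrogates flip the sign of each eigencoefficient independently (the
singleton procedure). This preserves the mean, the variance, and every
eigenvector's squared loading exactly — hence Moran's I exactly — while
scrambling the map's phase relative to the geometry.

**TFNBS.** The edgewise statistic (ANCOVA F for the group factor adjusting
for covariates; a two-sample T map for post hoc contrasts) is enhanced over
`n_steps = 100` thresholds equally spaced in (0, max F]: at each threshold
h, every supra-threshold edge accumulates (component extent)^E · h^H · dh
with E = 0.5, H = 2.25, where components are the connected node components
of the supra-threshold edge graph and extent is counted **in edges**
(the network-based-statistic tradition). The implementation walks
thresholds in descending order with an incremental union-find, so one
enhancement pass is near linear in the edge count. Family-wise error
control compares each edge's enhanced score with the permutation
distribution of the maximum enhanced score (group labels shuffled,
covariates fixed, add-one rule). Thresholds are scaled per statistic map
(its own maximum), which makes the enhancement scale-equivariant; enhanced
scores are monotone under scaling of the statistic map.

**Phenotype models.** PLS1 reports the squared correlation between the
first partial-least-squares scores and the phenotype (as a percentage),
with y-permutation significance. BBS reduces edges by PCA to 80% cumulative
variance fitted on each training fold, regresses component scores on the
phenotype, predicts held-out subjects, and reports the mean Pearson r over
100 repetitions of shuffled 10-fold CV; each permutation repeats one full
CV with reshuffled phenotype. SVM classification uses the same
PCA-to-80% reduction with a linear maximum-margin classifier (C = 1) and
stratified folds. Fold assignment shuffles subjects label-independently and
deals each class round-robin, which makes label inversion an exact symmetry
of the cross-validation. All permutation engines are seeded and use the
add-one rule, so p = 0 is impossible.

## Synthetic data

The generators are pure functions of (parameters, seed) — identical calls
are bit-identical — and Gaussian throughout; none of the downstream
statistics assumes heavier tails, and heavy-tail options are deferred.

- `make_toy_atlas`: mirrored cuboid blocks (21 left/right pairs + 6 midline
  by default = 48 regions, matching the structure of the 48-region WM
  atlas with its 42 lateralized regions). Cuboid geometry buys exact
  left/right voxel-count symmetry at the cost of anatomical realism.
- `simulate_subject_maps`: region voxels ~ N(μ_{r,s}, σ_{r,s}); homotopic
  partners blend parameters with weight = coupling (default 0.8), so
  coupling 1 gives identical distributions up to sampling noise and
  coupling 0 gives fully independent ones. Region base means spread
  uniformly over ±2 so unrelated regions are distinguishable.
- `simulate_sessions`: value = √ICC·subject + √(1−ICC)·noise, giving the
  target population ICC exactly.
- `simulate_twins`: member = √a²·G + √c²·C + √e²·E with G shared in MZ and
  correlated ½ in DZ pairs, so r_MZ = a²+c² and r_DZ = a²/2+c² by
  construction.
- `simulate_groups`: standard-normal edges with a planted
  connected-component shift of δ SD in one group (must form a single
  component, the detectable unit of the network-based statistic).

What passing tests on these fixtures do **not** show: robustness to
non-Gaussian morphometry, scanner/site effects, registration error,
spatially correlated noise within regions, or realistic WM geometry. The
fixtures validate the estimators and their calibration, not the imaging
pipeline.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale, chosen so every
stochastic check is decisive yet the whole suite stays light: ICC recovery
at 200 subjects × 3 sessions (±0.05), ACE recovery at 200+200 pairs
(±0.08), permutation-calibration checks at 200 permutations × 500 edges
(Kolmogorov–Smirnov), TFNBS null calibration at 20v20 subjects × 48
regions × 500 permutations × 50 replicates (empirical FWE ≤ 0.10 at
nominal 0.05) and power at δ = 1.5 SD (≥ 90% over 20 replicates), and
null adjusted-R² over 100 replicates (±0.02). Exhaustive graph-oracle
equivalence covers every connected graph on ≤ 5 nodes plus seeded random
6–8-node graphs. KDE agreement with the explicit kernel-sum oracle is
asserted at 1e−10, ICC/ANCOVA against sums-of-squares oracles at 1e−12.

## Known limitations

- Falconer ACE ignores measurement-error structure a likelihood fit would
  model; AE/CE submodels and bivariate genetic correlations are out of
  scope.
- The MSR singleton procedure yields at most 2^(R−1) distinct surrogates;
  for very small atlases with many requested surrogates, duplicates are
  possible.
- Per-pair KDE re-evaluation makes `build_network` O(R²·voxels·n_points);
  fine up to a few hundred regions, not intended for voxel-level graphs.
- ComBat-style site harmonization is deliberately not reimplemented; feed
  harmonized edge panels to the statistics directly.
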