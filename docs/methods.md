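# Methods

`vectorscape` models two complementary properties of a disease-vector
landscape — where the vector can live (habitat suitability) and how freely
it moves (genetic connectivity) — and integrates them into a single
planning map. The motivating system is the tsetse fly *Glossina
pallidipes* in Kenya and northern Tanzania, where suitability is informed
by trap records and connectivity by microsatellite genotypes from 29
sampling sites split by the Great Rift Valley into an eastern and a
western genetic cluster. The package ships a truth-known synthetic data
generator so the full pipeline can be exercised, and its statistical
behavior verified, without any field data.

## Genetic distances

Genotypes are diploid microsatellite calls (two alleles per individual per
locus, missing allowed only as a whole call). Site allele frequencies are
plain counts over non-missing calls; the allele support of a locus is the
union over all sites, so an allele unseen at a site has frequency 0.

The distance between sites is the Cavalli-Sforza & Edwards chord distance.
Per locus,

    cos θ_l = Σ_a sqrt(p_la · q_la),      D_l = (2/π) · sqrt(2 (1 − cos θ_l)),

and the multilocus distance is the mean of `D_l` over loci observed in both
sites (pairwise deletion — one reason chord distance is preferred for
microsatellite data with missing calls). `D_l` lies in `[0, (2/π)√2 ≈
0.9003]`, and so does the mean. Published implementations differ in how
they aggregate loci; a pooled variant `(2/π)·sqrt(2(1 − mean_l cos θ_l))`
is available via `cse_variant="pooled"`. The averaged form need not
satisfy the triangle inequality; nothing downstream relies on it.

Distances are computed for within-cluster site pairs only: between-cluster
divergence reflects ancient vicariance rather than the contemporary
landscape the connectivity model is after. Two clusters of 16 and 13 sites
give `16·15/2 + 13·12/2 = 198` pairs. Mantel tests (Pearson correlation of
distance matrices, one-sided permutation p-value `(1 + #{r* ≥ r})/(n_perm
+ 1)`) are provided to document the expected geographic-distance
confounding.

## Path features and geographic distance

Each site pair is summarized by the straight segment between the sites.
Segments are rasterized by supercover traversal (every cell the segment
touches; Bresenham can skip cells that thin diagonal features occupy), and
each environmental layer contributes the **median** of its values over the
path cells — medians rather than means so single extreme cells do not
dominate. Nodata cells are skipped; if more than half of a path is nodata
for some layer, that feature is flagged and the pair is dropped from model
input with a logged warning. Geographic distance is the sum of an all-ones
raster over the path cells — exactly the cell count, interpreted as km on
a 1-km grid; no geodesic correction is applied (paths are planar straight
lines). A sampling-effort layer (Gaussian kernel density of the site
locations, bandwidth 10 cell sizes by default — the source analyses do not
print a bandwidth) is summarized the same way. Distance and density
features let the forest absorb spatial autocorrelation instead of
misattributing it to environmental layers.

## Bioclimatic variables

`geo.compute_bioclim` derives the 19 standard bioclimatic variables from
monthly tmin/tmax/precipitation stacks. The season-dependent variables
(bio8–11, bio16–19) take user-defined named month windows rather than
hard-coded calendar quarters, because East African rainfall is bimodal and
rolling quarters misplace the wet/dry seasons; the default falls back to
the standard rolling three-month quarters. Wettest/driest seasons maximize
or minimize total precipitation per cell; warmest/coldest mean
temperature; ties go to the first-listed season. Standard deviations are
sample SDs (ddof=1) and bio15 is `100·sd(prec+1)/mean(prec+1)`, matching
the classic `biovars` convention so results are comparable with that
toolchain. bio3 is NaN where bio7 = 0.

## Suitability model

Presence cells (deduplicated to one per grid cell) scored 1 and random
background cells scored 0 form the response of a **regression** forest on
the per-cell environmental values — regressing the binary response yields
a continuous suitability score in [0, 1] (forest predictions are means of
leaf values). The design is 10 replicates of 100 background points drawn
uniformly over eligible (non-ocean) cells with seeds derived from one base
seed; each replicate yields a model, and the reported surface is the
per-pixel mean of the 10 projections (the source analyses report
replicate-wise metrics without stating the final aggregation; the mean is
this package's choice, with a pooled-model alternative straightforward to
assemble from the parts).

Fit quality is the forest's out-of-bag R²; variable importance is increase
in node purity — total RSS decrease from splits on a variable, averaged
over trees without sklearn's per-tree normalization — chosen over
permutation importance because it is not inflated by predictor
correlation. Discrimination is assessed by stratified 10-fold CV with AUC
(rank-based, ties half) and TSS (max over thresholds of sensitivity +
specificity − 1; the threshold search via the ROC curve is exactly
equivalent to brute-force enumeration of the unique scores). Forest
hyperparameters (500 trees, p/3 features per split, leaf size 5 — the
regression-forest conventions; none are printed in the source) live in
`ForestParams`.

A prior suitability map can be merged by per-pixel maximum
(`geo.combine_max`): for vector control, over-predicting presence is the
conservative error. Nodata in one input defers to the other.

## Connectivity model

Chord distance per pair is regressed on the path features (22 layer
medians + density median + geographic distance) with the same forest
conventions. The fitted model is projected per pixel by supplying the
pixel's own layer and density values with geographic distance fixed at 1 —
the predicted genetic distance across one kilometre of that environment.
Connectivity for mapping is `1 − scale01(predicted distance)`.

Evaluation is leave-one-**site**-out: all pairs touching the held-out site
are the test set, giving one RMSE per site (29 runs in the default
design); leave-one-site-out is used because a site's pairs share its
idiosyncrasies, so leaving out single pairs would leak. The null reference
re-runs the identical LOO procedure on responses permuted jointly over all
pairs, 100 times, each replicate summarized as the mean of its per-site
RMSEs; observed per-site RMSEs are compared to the null values with a
one-sided Welch t test (unequal variances, alternative observed < null).
Observed and null runs use identical forest settings so the comparison is
fair. A spatial variant predicts each test pair as the median of the
projected surface along the pair's path, measuring the accuracy of the
map rather than the model.

## Integration and post hoc analyses

Both surfaces are min-max scaled to [0, 1]. Cells with predicted
probability of presence strictly below 0.10 are masked from every
downstream map. The bivariate map cuts each surface into `n` quantile
(equal-count) classes over unmasked cells — 3 per axis by default, 9
joint classes, with a default corner-anchored palette — falling back to
equal-interval breaks when quantiles degenerate. Cells with identical
values share a class, so marginals are equal-count up to rounding (±1
when values are distinct).

Local correlation maps (per-cell Pearson r of a model surface vs a
predictor layer over a moving window, 21 cells by default) show where a
top-ranked predictor actually drives the response. The implementation
uses box-filter sums, with windows of fewer than 3 valid cells or zero
variance set to nodata, and shares the 10% mask. Expected environmental
change is mapped as `future − present` per pixel for the top predictors;
projecting the *models* under future climate is deliberately out of scope
(transferability to novel conditions is an unsolved problem), so only the
predictor deltas are mapped.

## Synthetic data generator

The generator emulates the statistical structure the models assume:

* **Landscape** — each layer is white noise smoothed with a Gaussian
  filter (`corr_length` cells, default 8 on a 100×140 grid of 1-km cells),
  standardized to mean 0, variance 1 over unmasked cells; layers are
  mutually independent in expectation. An optional smooth nodata blob
  (default 8% of cells) stands in for ocean/lakes. Defaults generate 22
  layers, mirroring the real stack (19 bioclim + slope + altitude + river
  density).
* **Resistance and divergence** — a log-linear resistance surface
  `exp(Σ w_j x_j)` over designated driver layers (default: one driver,
  weight 1). The cost of a site pair is the sum of resistance over its
  supercover path cells, so cost grows with both path length (isolation by
  distance) and adverse environment (isolation by resistance). Latent
  per-site allele frequencies are built by embedding each cluster's
  `divergence_rate × cost` matrix in Euclidean space (classical MDS,
  negative eigenvalues clipped) and perturbing a shared ancestral
  Dirichlet frequency vector along random sum-zero directions scaled by
  the embedding coordinates. Directions are normalized in the chord
  metric (`Σ u²/ancestral = π²`), which makes expected chord distance
  approximately equal to the embedding distance at small divergence —
  i.e., approximately linear in path cost, the regime the recovery tests
  need. The default `divergence_rate = 0.002` CSE-units per unit cost
  puts pairwise distances in the 0.1–0.3 range typical of within-cluster
  microsatellite data in this system. A fixed 0.5-chord-unit offset
  separates the two clusters (suppressed at rate 0 so the no-divergence
  limit is exact). Genotypes are two independent allele draws per locus
  (11 loci, 8 alleles, 23 individuals/site by default; per-site sample
  sizes in the real data vary 7–46 with mean ≈ 23), with 2% of calls
  missing completely at random.
* **Presences** — cells sampled without replacement with probability
  proportional to a logistic function of the driver layers. The default
  link is sharp (weight 8, intercept −12, i.e. presence concentrated in
  the top ~7% of the driver): with presence-*background* sampling the
  background overlaps the presence distribution, and a moderate logistic
  slope caps the best achievable AUC near 0.85, whereas real trap data
  for this system are nearly separable (AUC ≈ 0.99); the sharp link
  reproduces that regime. Default 349 points, matching the trap-location
  count.

What the generator does **not** emulate: linkage and mutation processes
(no coalescent), temporal population fluctuations, spatially biased trap
placement, correlated environmental layers, and anisotropic dispersal.
Passing recovery tests therefore demonstrate that the pipeline recovers
known structure of this idealized kind, not that the real study's effect
sizes are correct.

## Numerical and degenerate-input choices

* Cells are half-open intervals; points on the far extent edge clamp into
  the last row/column; cell centers are the evaluation points everywhere.
* Supercover traversal resolves exact corner crossings by emitting both
  side cells before the diagonal; path direction is canonicalized so
  reversing endpoints exactly reverses the cell list.
* `cos θ` is clipped at 1 before the square root; constant responses,
  constant layers to `scale01`, single-class CV folds, empty geometry
  lists, and mismatched grids are rejected with explicit errors.
* Quantile-break ties share a class; degenerate breaks fall back to
  equal-interval with a logged warning.
* All randomness flows from user-supplied integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; the full pipeline is
  byte-reproducible (verified by test).

## Problem sizes

The default configuration (grid 100×140, 29 sites, 198 paths, 349
presences, 500-tree forests, 100-replicate null at 100 trees) runs in a
few minutes on one core; the test suite's recovery and calibration loops
use 10–20 seeds with 25-replicate nulls and 25–100-tree forests, and the
end-to-end determinism check uses a reduced 50×70 / 11-site design. These
sizes are the package's desk-scale study conditions; all are config, so
larger designs are a YAML edit away.

## Known limitations

* ESRI ASCII grids (plain text) are the raster interchange format; there
  is no GeoTIFF/CRS-aware reprojection — grids must already be aligned.
* Straight-line paths only; no least-cost or circuit-theory routing.
* Genetic cluster labels are an input (the generator assigns them); the
  package does not infer population structure.
* The connectivity projection applies one fitted model across both
  clusters' territory, although no cross-cluster pair ever enters
  training.
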