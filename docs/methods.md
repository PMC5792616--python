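# Methods

`ridgescan` implements a multiscale landscape-genomics workflow for dominant
(presence/absence) markers sampled along a topographically heterogeneous
alpine ridge: terrain habitat proxies are derived from a very-high-resolution
DEM at a dyadic ladder of resolutions, fine-scale population structure is
inferred without population-genetic equilibrium assumptions, spatial genetic
autocorrelation is quantified with balanced distance classes, and each locus
is scanned for associations with each terrain variable at each resolution
using binomial mixed models with DEM-pixel random intercepts.  This note
records the models, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish.

## Raster model and the resolution pyramid

Rasters are single-band, north-up, square-celled grids in one projected
metric frame (no reprojection; the CRS is an opaque label).  Cell values
represent cell centers; the stored georeference is the outer corner of the
top-left cell, converted from/to the lower-left convention of ESRI ASCII
grids at the I/O boundary.  Pixel membership is half-open (a point on a
shared edge belongs to the larger row/column index) and closed on the outer
maximum edge, so every in-bounds point maps to exactly one pixel — this
mapping defines the random-effect grouping of the association scan, so it
must be unambiguous.

Each pyramid level doubles the cell size: the surface is low-pass filtered
with the separable discrete cubic B-spline kernel [1, 4, 6, 4, 1]/16 (mirror
boundary) and decimated by averaging 2x2 blocks, which places output cell
centers on block centroids and keeps the top-left origin fixed.  Constants
and linear ramps pass through exactly in the interior, the grid mean is
preserved by the block average, and zero-mean noise loses variance at every
level.  The spline order and the boundary rule are package choices; only the
x2 ladder itself (0.5, 1, 2, 4, 8 m) is inherited from the workflow the
package implements.  Cells whose filter support touches nodata become nodata
(conservative propagation).

## Terrain variables

Twelve variables are derived per pyramid level; measured altitude (Alt) comes
from the field sample table, not the DEM.

- **Slope / aspect** — Horn's 3x3 weighted finite differences; aspect is the
  steepest-descent direction clockwise from north; cells flatter than 0.01
  degrees are flagged (aspect undefined). Horn's stencil is the standard
  noise-robust choice on sub-meter DEMs.
- **Nor / Eas** — cosine and sine of aspect; flat cells are set to the
  neutral value 0.
- **VRM** — vector ruggedness: 1 minus the norm of the mean unit surface
  normal in a 3x3 window; 0 on planes regardless of slope.
- **TOP / TON** — positive/negative topographic openness: mean over 8
  azimuths of the zenith (nadir, after sign inversion) angle of the line of
  maximum elevation along the profile out to a 50 m radius. Profiles are
  sampled bilinearly at one-cell steps; bilinear sampling makes every plane
  give exactly pi/2, which nearest-neighbor sampling does not.
- **SVF** — sky-view factor: mean of cos^2 of the non-negative horizon angle
  over 16 azimuths within 50 m; 1 on an unobstructed plane.
- **SWI** — wetness index ln(a / tan beta): specific catchment area from
  Freeman multiple-flow-direction accumulation (exponent 1.1) on the
  sink-filled surface, times the cell size; tan beta floored at 0.001.
  Depressions are filled by priority flood with minimal raising.
- **FPL** — D8 flow-path length; diagonal steps count cell x sqrt(2). The
  `direction` parameter selects the downstream distance to the grid edge
  (default) or the longest upstream path reaching the cell. The two answer
  different questions: crest positions have near-zero *upstream* length but
  the longest *downstream* paths, so habitat contrasts between crest and
  flank populations are read on the upstream variant.
- **WEX** — isotropic wind exposure: per azimuth, the exp(-0.01/m)-weighted
  mean of the slope angles from the focal cell to the profile (positive when
  the cell overlooks the terrain), mapped through (2/pi) arctan and averaged
  over 8 azimuths around 1; the 300 m far field is sampled with doubling,
  width-weighted strides (a quadrature of the same decaying integral).
  Exactly 1 on any plane; > 1 on crests; < 1 in hollows. No prevailing wind
  direction is assumed.
- **Ti6 / Ti12** — monthly clear-sky irradiation (kWh/m2) for June and
  December at latitude 46.433 N: solar position from the standard
  declination/hour-angle formulas at 60-minute steps; direct beam
  1.367 kW/m2 x tau^(1/sin h) projected on the tilted surface and zeroed when
  the sun sits below the DEM horizon in its azimuth (16-azimuth horizon
  stack, 100 m search radius, linear interpolation in azimuth); isotropic
  diffuse 0.3 x 1.367 x (1 - tau^(1/sin h)) weighted by SVF; lumped
  transmittance tau = 0.7. This is a deliberately simple lumped-parameter
  model: it is validated against an analytic flat-plane integral and by
  ordering properties (June > December; sun-facing steep slopes gain in
  December), not against any external GIS implementation's absolute values.

Search radii (50 m openness/SVF, 300 m WEX, 100 m solar horizon) are exposed
in `TerrainConfig` and recorded in output metadata; published workflows of
this kind rarely state them, so they are package defaults, chosen at typical
geomorphometric scales relative to the 1.2 km study extent.

## Synthetic landscape and genotypes

The generator emulates the study conditions end to end so that every stage is
testable without field data: a ~1.2 km ridge at 0.5 m resolution spanning
1,864-2,043 m; cluster sampling of ~361 individuals (4x4 m areas at random
0-25 m gaps, four 2x2 m plots each, plots holding at least five plants, areas
retained with probability 0.35 to mimic patchy plant presence); 233
polymorphic dominant loci with symmetric scoring errors at the
replicate-estimated rate 2.93% and a minor-variant frequency filter at 0.05
(failing loci are redrawn so the matrix keeps its size).

Neutral structure is the package's own minimal construction (no coalescent or
explicit gene flow): individual i has admixture q*_i =
logistic((x_i - center)/120 m + N(0, 0.4)) along the ridge axis, and a
neutral locus draws bands with probability q* p_A + (1 - q*) p_B, where the
pool frequencies differ by a per-locus gap ~ N(0, 0.3).  Five "adaptive" loci
instead follow logistic(beta0 + beta1 z) in a standardized terrain variable
(defaults: Alt, TON at 0.5 m, Nor at 1 m, Ti12 at 1 m, WEX at 0.5 m, with
|beta1| between 1.2 and 1.5).

Two generator choices exist specifically to keep neutral structure and
environment statistically separable, which the real system does not
guarantee:

1. the along-ridge crest profile is a full-period cosine (even about the
   ridge midpoint) while the cline is odd about it, and the micro-topography
   noise is band-limited to wavelengths below 50 m — unconstrained red noise
   carries random broad trends that correlate spuriously (|rho| up to ~0.4)
   with any equally smooth cline;
2. across-ridge area offsets cycle through a shuffled balanced deck rather
   than being drawn independently — with only ~18 areas the effective sample
   size for between-area habitat contrasts is the area count, and iid offsets
   routinely confound across-ridge habitat with position along the ridge.

Consequently, passing the type-I-error checks here shows the scan is
calibrated *when structure and environment are orthogonal*; it does not show
that pixel random intercepts remove genuine structure-environment
confounding (they do not — in the field system the two gene pools really do
occupy different habitats, and associations there carry that ambiguity).
Conversely, the synthetic pools are cleaner than real dominant-marker data,
so fuzzy memberships at m = 1.02 come out nearly hard and fewer individuals
are called admixed than in the field data.

## Population structure

Loci failing min(f, 1-f) > 0.05 are dropped; missing genotypes are mean-
imputed per locus for clustering only (never for the scan).  K-means
(Euclidean, 10 restarts) over K = 2..20 is scored by the Calinski-Harabasz
criterion [between-SS/(K-1)]/[within-SS/(n-K)]; the criterion map is
reported, not just the argmax, so a flat profile is visible.  Admixture
coefficients come from fuzzy c-means with fuzzification m = 1.02 (memberships
proportional to squared distance^(-1/(m-1)), computed in log space; centroids
as membership^m-weighted means; convergence at 1e-8 centroid movement).
Runs are aligned with a greedy CLUMPP-style search: random input orders,
each new run permuted to maximize G = 1 - ||Q1 - Q2||_F / sqrt(2n) against
the running average, best mean pairwise G kept.  At K = 2 the greedy search
provably explores both orientations per run and is tested against exhaustive
enumeration.  Defaults are desk-scale (50 runs, 200 greedy repeats); the
study-scale values (1,000 runs, 10,000 repeats) are plain config changes.
Individuals with aligned membership > 0.8 / < 0.2 are assigned to
populations A / B; boundary values are admixed (strict inequalities).

## Spatial autocorrelation

The relationship coefficient for 0/1 data is the frequency-centered
cross-product r_ij = sum_l (x_il - p_l)(x_jl - p_l) / sum_l p_l(1 - p_l) over
loci scored in both individuals — a Hardy-style dominant-marker estimator
with no inbreeding correction, chosen because its arithmetic is fully
testable; reference allele frequencies are the pooled sample frequencies.
Distance classes are rank chunks of the stably sorted pairwise distances, so
per-class pair counts are equal to within one even under tied distances
(boundary ties go to the lower class whenever distances are distinct).
Significance per class is a two-tailed permutation test with add-one
correction, permuting individual locations while genotypes stay fixed; the
per-class significance level is 0.05/n_classes.

## Gene-environment association scan

For locus y, covariate x (standardized per variable x resolution by default)
and grouping g:

    y_i ~ Bernoulli(logit^-1(b0 + b1 x_i + u_g)),  u_g ~ N(0, sigma_u^2)

The marginal likelihood is maximized under the Laplace approximation: the
per-group penalized mode is found by an inner Newton iteration (the per-group
problem is concave), and (b0, b1, log sigma_u) are optimized by Nelder-Mead
with warm-started modes.  Raster variables group by DEM pixel id at the
variable's resolution; Alt, X, Y and the membership coefficient group by
sampling plot.  The null (constant) model is fitted once per locus and
grouping and reused across variables.

Numerical safeguards, each visible in the fit record:

- sigma_u is bounded above at e (log sigma <= 1, quadratic penalty): with
  mostly-singleton binary groups the Laplace surface grows a spurious
  optimum at large sigma that the exact marginal likelihood does not have;
- a full fit that ends below its nested null (impossible at the true optima)
  is refitted from the null solution;
- the sigma_u -> 0 limit is the exact logistic-regression likelihood, used
  both as a fallback and as the reduction oracle in tests;
- an adaptive Gauss-Hermite evaluation (Laplace is its 1-node case) is
  provided as a cross-check of the approximation; the full fit is also
  verified against lme4's `glmer` (nAGQ = 1) in the test suite.

AIC counts k = (#fixed effects) + 1 variance component (null 2, full 3), so
lrt_stat = 2 dlogLik = AIC_null - AIC_full + 2 holds for every record; this
convention is pinned by reconstructing published p-values from published AIC
pairs.  The LRT p-value is the chi-square(1) upper tail (the variance
component is present in both models, so the boundary issue does not arise for
the fixed-effect test).  Significance is Bonferroni over all attempted cells
(alpha / #records); with the full 233 x 13 x 5 family this reproduces the
3.3e-6 level.  Non-convergent or inestimable cells are flagged and excluded
from significance lists, never dropped silently.

## Habitat comparison

Per (variable, resolution), population A and B values are compared with the
tie-corrected Kruskal-Wallis test (admixed individuals are summarized
descriptively; a 3-group variant is available).  Because the multiplicity
family behind this kind of table is ambiguous, both readings are computed:
Bonferroni over the global variables x resolutions family and per-variable
over resolutions; the per-variable summary reports the best resolution's p
and the globally significant resolutions.

## Problem sizes and runtime choices

Defaults are sized for a single CPU: the default landscape is 2,400 x 192
cells at 0.5 m; the scan-recovery studies use the variables carrying planted
links (Alt + 4 terrain variables x 5 resolutions, ~5,400 models per
replicate) over 20 genotype replicates in the test suite and 12 in the
acceptance script; structure uses 50 c-means runs with 200 greedy repeats;
correlograms use 199 permutations for calibration checks and 999 in the
pipeline (9,999 remains a config value).  Restricting the scan family makes
the Bonferroni threshold *stricter* per test than the full-family level, so
the power results are conservative.

## Known limitations

- The Laplace likelihood is biased for binary responses in very small groups
  (the AGQ cross-check shows O(1) total offsets); LRT differences are far
  less affected, and the lme4 oracle confirms parity with the standard tool.
- sigma_u estimates at the bounds are reported as boundary values, not
  treated as interior estimates.
- The solar model omits atmospheric refraction, ground reflection, and
  anisotropic diffuse radiation; it is a ranking proxy, not an energy model.
- The generator's neutral model is phenomenological (cline + two pool
  frequencies); it produces realistic marginal statistics but no linkage,
  no kin structure, and no drift history.
- Openness/SVF/WEX depend on their search radii; values are comparable only
  within one configuration, which is why the radii travel in the metadata.
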