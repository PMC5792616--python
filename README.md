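# ridgescan

Multiscale landscape genomics for dominant markers: derive topographic
habitat proxies from a very-high-resolution digital elevation model (DEM) at
several spatial resolutions, infer fine-scale population structure from
presence/absence (AFLP-like) genotypes, quantify spatial genetic
autocorrelation, and scan every locus for gene-environment associations with
binomial mixed models that use DEM pixels as random effects.

The package is aimed at landscape geneticists working on sessile organisms in
topographically heterogeneous terrain — settings where micro-habitat varies
over meters, where the informative spatial resolution of an environmental
proxy is unknown a priori, and where polyploidy or dominant markers rule out
methods that need Hardy-Weinberg assumptions.

## The model at the core

For locus *l* with band indicator *y*, environmental covariate *x* (one
terrain variable at one resolution, standardized) and DEM pixel *g* at that
resolution:

```
y_i ~ Bernoulli( logit^-1( β0 + β1 x_i + u_g ) ),    u_g ~ N(0, σ_u²)
```

fitted by maximizing the Laplace-approximated marginal likelihood (verified
against `lme4::glmer`, nAGQ = 1).  Pixels absorb the pseudo-replication of
individuals sharing a cell — the coarser the resolution, the more individuals
per pixel.  Significance is a χ²(1) likelihood-ratio test against the
constant model, Bonferroni-corrected over the loci × variables × resolutions
family; AIC uses k = #fixed effects + 1 variance component, so
`lrt_stat = AIC_null − AIC_full + 2` for the one added slope.  For
non-raster covariates (measured altitude, coordinates, admixture
coefficient) the sampling plot replaces the pixel as the random effect.

Around this scan the package provides: a dyadic DEM pyramid (cubic B-spline
low-pass + 2×2 decimation), twelve terrain derivatives (slope/aspect,
northness/eastness, vector ruggedness, positive/negative openness, sky-view
factor, wetness index, flow-path length, wind exposure, June/December solar
radiation), K-means + Calinski-Harabasz cluster-number selection, fuzzy
c-means admixture (m = 1.02) with CLUMPP-style greedy run alignment,
balanced-distance-class correlograms with permutation tests, Kruskal-Wallis
habitat comparisons, and a synthetic-landscape generator that plants known
gene-environment links for end-to-end validation.  See `docs/methods.md` for
the full model descriptions and design choices.

## Worked example

Simulate a small ridge population with one planted association (locus
`L0001` linked to negative topographic openness, TON, at 1 m), then run
structure inference and the scan:

```python
import numpy as np
from ridgescan import synth, terrain, structure, gea
from ridgescan.pyramid import ResolutionLadder, build_pyramid

cfg = synth.ScenarioConfig(seed=7, ridge_length=400.0, ridge_width=64.0,
                           n_individuals=120, n_loci=80, n_adaptive=1,
                           adaptive_links=(synth.AdaptiveLink(0, "TON", 1.0, 0.0, 1.5),))
dem = synth.make_ridge_dem(cfg)
samples = synth.make_sampling(cfg, dem)
pyr = build_pyramid(dem, ResolutionLadder())
stack = terrain.compute_stack(pyr, terrain.TerrainConfig(variables=("TON",)))
env = terrain.extract_stack(stack, samples)
gm, truth = synth.simulate_genotypes(cfg, dem, samples, stack)

res = structure.run_structure(gm, k_range=range(2, 9), n_runs=20,
                              greedy_repeats=50, seed=1)
print(f"K = {res.K}, mean pairwise similarity G = {res.similarity:.3f}")

scan_df = gea.scan(gm, env, samples, pyr, membership=res.membership,
                   cfg=gea.ScanConfig(position_vars=("Alt",)))
print(f"models fitted: {scan_df.attrs['n_tests']}, "
      f"Bonferroni threshold = {scan_df.attrs['bonferroni_threshold']:.2e}")
top = scan_df.dropna(subset=["p"]).nsmallest(3, "p")
print(top[["locus", "variable", "resolution", "p", "beta1",
           "aic_null", "aic_full"]].to_string(index=False))
```

prints

```
K = 2, mean pairwise similarity G = 0.872
models fitted: 480, Bonferroni threshold = 1.04e-04
locus variable  resolution            p    beta1   aic_null   aic_full
L0001      TON         1.0 1.586198e-13 1.760304 185.586417 133.126113
L0001      TON         2.0 6.607776e-09 1.618261 168.812120 137.165151
L0001      TON         0.5 5.293534e-08 1.087903 189.545909 161.939709
```

Two gene pools are recovered along the ridge, and the only locus below the
Bonferroni line is the planted one — most significant at its generating 1 m
resolution, weaker one step away, i.e. the resolution profile that motivates
scanning a whole pyramid instead of a single grid.  The AIC columns satisfy
`lrt_stat = AIC_null − AIC_full + 2` for every row.

The same stages are available as a CLI (`ridgescan simulate | pyramid |
terrain | structure | autocorr | scan | habitat | run | report`); `ridgescan
run` executes the whole pipeline from one YAML config, writes
`membership.csv`, `correlogram.tsv`, `scan.tsv`, `habitat.tsv` plus a report
with resolution-profile plots, and is resumable and byte-for-byte
reproducible under a fixed seed.

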