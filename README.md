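# toxscape

Distance-decay exposure estimation from point-source toxic releases, with
spatial regression and AIC-based comparison of exposure models.

## The problem

Registries of industrial chemical releases (such as the EPA's Toxic Release
Inventory) record where pollution is emitted and in what volume, but health
analyses need to turn those point sources into a per-county *exposure*.
Most studies use crude geography — a county is "exposed" if it contains a
site, or lies within a fixed buffer of one — which ignores how impact fades
with distance. `toxscape` implements the spatial-interaction (gravity
model) alternative: the impact of site *i* with release volume `t_i` on
county *j* at centroid distance `d_ij` is computed under six families,

```
containment:  k_ij = t_i^α · 1[site i in county j]
buffer:       k_ij = t_i^α · 1[d_ij ≤ T]
power:        k_ij = t_i^α / d_ij^θ
exponential:  k_ij = t_i^α · exp(−θ d_ij)
cutter:       k_ij = t_i^α · (1 − (d_ij/T)²)^θ · 1[d_ij ≤ T]
external:     precomputed per-county risk score (e.g. RSEI)
```

summed into the cumulative county exposure `K_j = Σ_i k_ij`, and compared
by how well each explains an age-adjusted outcome rate in a multivariate
regression alongside demographic and behavioral covariates. Because
county outcomes are spatially autocorrelated, the package fits not only
OLS but also maximum-likelihood **spatial lag** (`Y = ρWY + Xβ + ε`) and
**spatial error** (`Y = Xβ + u, u = λWu + ε`) models over distance-band or
queen-contiguity weights `W`, and ranks families and parameterizations by
AIC. It is aimed at environmental-health and environmental-justice
researchers who want the exposure-model choice itself on the table.

The package also ships a seeded synthetic-scenario generator with known
ground truth (lattice counties, urban clustering of sites, lognormal
volumes, a chosen true decay family, optional spatially autocorrelated
outcome processes), so every stage — kernels, weights, ML estimators,
grid search, model selection — is testable without restricted data.

## Worked example

```python
import numpy as np
from toxscape import (county_config, simulate, GridSpec, ExposureComparison,
                      distance_band_weights, min_connecting_threshold)

# 20x20 lattice of 20-mile counties; true exposure = buffer, T=100 miles;
# spatial-error outcome process with lambda = 0.5
sc = simulate(county_config(seed=42, spatial_process="error",
                            spatial_coefficient=0.5))

grid = GridSpec(alphas=(1.0,), thetas=(1.0, 2.0, 5.0),
                thresholds=tuple(np.arange(50.0, 500.1, 50.0)),
                log10_options=(True,), release_sets=("all_carcinogen",))
thr = min_connecting_threshold(sc.regions)          # smallest band with no isolates
w = distance_band_weights(sc.regions, thr).row_standardize()

model = ExposureComparison(sc.sites, sc.regions, weights=w, grid=grid)
results = model.fit()
print(results.summary())
```

prints

```
Best parameterizations:
     family    release_set  alpha  theta  threshold  log10
containment all_carcinogen    1.0    NaN        NaN   True
     buffer all_carcinogen    1.0    NaN      100.0   True
      power all_carcinogen    1.0    1.0        NaN   True
exponential all_carcinogen    1.0    1.0        NaN   True
     cutter all_carcinogen    1.0    2.0      150.0   True

AIC by family and regression model:
model              error          lag          ols
family
buffer       2475.060204  2480.192761  2486.596675
containment  2691.161234  2713.207089  3096.112083
cutter       2533.108913  2543.629729  2553.152207
exponential  2692.135981  2714.282841  3102.470781
no_term      2690.284880  2712.412542  3100.522500
power        2682.884177  2667.740103  2874.637188
minimum-AIC family (error): buffer
minimum-AIC family (lag): buffer
minimum-AIC family (ols): buffer
```

The grid search recovers the generating threshold (buffer, T = 100 miles)
and the buffer family attains the minimum AIC under all three regression
models, with the quadratic cutter — which approaches a buffer as θ → 0 —
closest behind; the spatial models beat OLS because the outcome carries a
genuine error-process autocorrelation. The full fit behind any cell is
available, e.g. `results.fits[("buffer", "error")].summary()` shows the
exposure coefficient 0.482 ± 0.016 (truth: 0.5) and λ̂ with its Wald
p-value.

A command-line surface wraps the same stages:

```
toxscape simulate --grid-side 10 --n-sites 50 --seed 7 --out scenario/
toxscape weights  --regions scenario/regions.csv --auto-threshold --out w.gal
toxscape exposure --sites scenario/sites.csv --regions scenario/regions.csv \
                  --family cutter --alpha 1 --theta 5 -T 500 --log10 on \
                  --release-set lung_compound --out impacts.csv
toxscape compare  --config run.yaml
```

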