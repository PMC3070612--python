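# Methods

## Problem and model

`toxscape` estimates the exposure of areal units (counties) to point-source
toxic releases and asks which spatial form of that exposure best explains an
age-adjusted health-outcome rate. The per-site impact of a release of
volume `t_i` (pounds) on county `j` at centroid distance `d_ij` (miles) is
computed under six families:

| family       | `k_ij`                                            | parameters |
|--------------|---------------------------------------------------|------------|
| containment  | `t_i^α` if site i lies in county j, else 0         | α |
| buffer       | `t_i^α` if `d_ij ≤ T`, else 0                      | α, T |
| power        | `t_i^α / max(d_ij, d_floor)^θ`                     | α, θ |
| exponential  | `t_i^α · exp(−θ d_ij)`                             | α, θ |
| cutter       | `t_i^α (1 − (d_ij/T)²)^θ` if `d_ij ≤ T`, else 0    | α, θ, T |
| external     | precomputed per-county risk score (RSEI-style)     | — |

The power and exponential kernels are the classical spatial-interaction
(gravity-model) decay forms; the gravity model's destination-mass term
`p_j^β` is fixed at 1 (β = 0) because the outcome is an age-adjusted *rate*,
not a count. The cutter family is a quadratic decay with a hard cutoff: it
is anchored at `t^α` at zero distance, nonincreasing on `[0, T]`, zero
beyond `T`, and converges pointwise to the buffer kernel as θ → 0⁺. County
exposure is the cumulative impact `K_j = Σ_i k_ij` over the selected release
set (all carcinogens; lung carcinogens; lung carcinogens plus their
compound-category releases). Because release volumes span orders of
magnitude and are approximately lognormal, both raw and log10-transformed
volumes are supported (volumes below 10 lb are floored at 10 before the log
so effective volumes stay positive).

The outcome model is a linear regression of the rate `Y_j` on covariates
`X_j` plus `K_j`, fitted three ways:

* **OLS** — `Y = Xβ + ε`;
* **spatial lag (ML)** — `Y = ρWY + Xβ + ε`: the outcome depends on
  neighbors' outcomes through a row-standardized weights matrix `W`;
* **spatial error (ML)** — `Y = Xβ + u`, `u = λWu + ε`: the disturbance is
  spatially autoregressive.

Families (and parameterizations within a family) are ranked by AIC =
−2 logL + 2k, with k counting the coefficients, the error variance, and the
spatial coefficient where present; this makes the three model classes
directly comparable (the OLS likelihood uses the ML variance RSS/n, not
REML, for the same reason).

## Estimation details

Both spatial models are estimated by maximizing the profile log-likelihood
of the autocorrelation coefficient: at each candidate ρ (or λ), β and σ²
have closed forms, and the Jacobian term log|I − ρW| is evaluated as
Σ log(1 − ρω_i) over the eigenvalues ω_i of `W`, computed once per weights
object by dense eigendecomposition and cached (exact and fast up to a few
thousand regions, which covers the ~3,100-county national scale). The
admissible interval is (1/ω_min, 1/ω_max) — (−1, 1) for row-standardized
weights. A 64-point coarse scan brackets the optimum and a bounded scalar
search shrinks the interval to 1e-6; the procedure is deterministic with no
random starts. At a coefficient of exactly 0 both profile likelihoods reduce
algebraically to the OLS likelihood (the models nest), which the tests check
to 1e-10.

Standard errors come from the inverse numerical Hessian (central
differences) of the full log-likelihood in (β, spatial coefficient, σ²) at
the optimum; p-values are Wald/normal. OLS inference is the usual t-based
inference via statsmodels.

Weights construction keeps the binary convention (1 for neighbors, 0
otherwise): distance-band weights link counties whose centroids lie within a
threshold, with the boundary *included* (a pair at exactly the threshold are
neighbors), and queen contiguity links regions sharing any boundary point.
The default band threshold is the minimum connecting distance — the largest
nearest-neighbor distance over all counties — which is the smallest band
leaving no county isolated. Row standardization is applied (and recorded as
a flag) before ML fitting. Isolated regions are permitted in weights objects
with a logged warning, but the spatial regressions refuse them unless
explicitly overridden, since an empty row silently turns the spatial term
off for that observation.

Diagnostics: global Moran's I with a one-sided (greater) permutation
p-value over seeded permutations; variance inflation factors computed per
column against all others (intercept included), reporting `inf` on perfect
collinearity rather than raising; and deterministic backward elimination
that drops the least significant covariate until all remaining terms beat a
significance threshold, with the exposure term protectable.

## The experiment pipeline

`grid_search` evaluates one family's full parameter Cartesian product
(defaults: α, θ ∈ {1.0, 1.5, …, 5.0}; T ∈ {5, 10, …, 500} miles; both
volume transforms; all three release sets) by OLS AIC, with ties broken
lexicographically by smallest (T, θ, α). Grid search uses OLS only:
parameterizations that perform well under OLS also perform well under the
spatial regressions, so the costlier spatial fits are reserved for the
selected parameterizations. `build_comparison` then fits all three model
classes for each family's best spec plus a covariates-only baseline (and
the external passthrough when present) with one fixed covariate set, so
every AIC in the table is comparable; pruning, when requested, runs after
family selection. `stratified_r2` refits the OLS specification within each
rural-urban continuum code (codes 0–3 metropolitan, 4–9 nonmetropolitan),
skipping strata with too few observations. `urban_source_share` decomposes
each county's `K_j` into the percentage contributed by sites whose home
county is metropolitan; counties with `K_j = 0` get a missing value, never
a fabricated 0.

## Synthetic scenarios

Real county mortality, release inventories and covariate files are
restricted or external, so the package generates scenarios with known
ground truth. The generator emulates:

* **geometry** — a `grid_side × grid_side` lattice of square counties,
  `cell_size` miles on a side (1 planar unit = 1 mile). The county-scale
  conditions (`county_config`) use a 20 × 20 lattice of 20-mile counties —
  a 400 × 400-mile domain in which a 100-mile threshold is identifiable
  within a 5–500-mile search grid;
* **urbanization** — a contiguous block of metropolitan counties (codes
  0–3) grown in shells from one corner, covering ≈ `urban_fraction` of
  cells (default 0.25); remaining counties draw codes 4–9;
* **sites** — 80 release sites by default, placed uniformly within
  counties but 4× more likely per unit area in metropolitan counties
  (mimicking the clustering of industrial facilities); volumes are
  `10^Normal(4, 1)` pounds — centered at 10,000 lb and spanning orders of
  magnitude, approximately lognormal as real release volumes are; each site
  carries one of the three chemical-class labels;
* **covariates** — five continuous covariates from a multivariate normal
  with exchangeable correlation 0.3 plus one binary regional indicator
  (western half of the domain): enough structure to exercise VIF and
  pruning without replicating any particular covariate list;
* **outcome** — `Y = 70 + Xβ + γK + ε` with default effects
  β = (3, −2, 1.5, 0, 0, −4), γ = 0.5 on a true buffer exposure (T = 100
  miles, log10 volumes) and ε ~ N(0, 5²), on a mortality-like scale of
  deaths per 100,000. With these defaults the exposure term's spatial
  standard deviation (≈ 19) is several times the noise SD — a deliberately
  strong effect, so that family-recovery experiments test the selection
  machinery rather than raw power. Optional spatial processes transform
  the mean + noise through `(I − ρW)⁻¹` (lag) or add `(I − λW)⁻¹ε` (error)
  over row-standardized queen weights, which are exact on the lattice.

Every stage draws from an independent child stream of the configured seed
(SeedSequence spawning), so scenarios are bit-identical across runs and
adding a stage never perturbs earlier draws.

What the generator does **not** emulate: irregular county geometry and
areas, population-weighted centroids, temporal lag structure between
release years and outcome years, chemical-specific toxicity, anisotropic
transport, and realistic covariate marginals. Passing tests therefore
demonstrate the correctness and calibration of the estimators and the
selection machinery under a controlled generating process — not that any
particular decay family describes real releases.

## Numerical choices

* Power-kernel distance floor `d_floor` = 1 mile (configurable): the
  gravity kernel is singular at d = 0 and site coordinates can coincide
  with centroids on synthetic lattices.
* Volume floor 10 lb before log10; affected sites are counted in a warning.
* α applies as an exponent (`t^α`), not a multiplier.
* Boundary conventions: `d = T` is inside buffer and cutter; `d =`
  band threshold is a neighbor.
* Degenerate exposures (constant K, e.g. an empty release set) are dropped
  from the design with the comparison row flagged, rather than producing a
  singular fit.
* Rank-deficient designs raise immediately, naming the collinear columns.
* Eigenvalue-based log-determinants take the real part of the complex log
  sum; row-standardized weights from symmetric binary structures have real
  spectra up to roundoff.
* Miles are the canonical distance unit; lon/lat columns switch to
  great-circle distances on a sphere of radius 3958.8 miles; kilometers
  convert at 1.609344 km/mile.

## Problem sizes used in the checks

The validation suite uses 20-seed recovery runs at n = 400 counties
(20 × 20 lattice), a reduced recovery grid (α = 1; θ ∈ {1, 2, 5};
T ∈ {50, 100, …, 500}; log10 volumes; one release set), 200-replicate null
calibrations at n = 196, dense ρ/λ profile-likelihood scans at step 1e-4 on
a 7 × 7 lattice, and brute-force oracles for distances, connectivity
thresholds, and cumulative impacts on instances up to 20 × 20. The
acceptance script runs the same county-scale experiment once plus a
10-seed λ-recovery average.

## Known limitations

* The spatial ML estimators use dense eigendecomposition; beyond ~5,000
  regions a sparse log-determinant method would be needed.
* One exposure family per regression; multi-family mixtures are out of
  scope.
* AIC differences between non-nested families are descriptive rankings,
  not formal tests.
* The spatial models' inference is Wald/asymptotic; small-sample p-values
  for ρ and λ should be read cautiously.
* Backward elimination inherits the usual caveats of stepwise selection;
  it is provided because it is the procedure under study, not as a
  recommended inferential tool.
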