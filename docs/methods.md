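# Methods

This note documents the statistical model, the estimator choices, the
synthetic-data generator that supplies ground truth, and the numerical and
design decisions a maintainer should know about.

## Data model and design

The analysis consumes a plot table and a tally table in the style of a
national forest inventory. Plots are a spatially balanced probability
sample with one plot per 24 km² in the southern stratum ("CA-OR") and one
per 26.6 km² in the northern stratum ("WA"); the km²-per-plot of a plot's
stratum is its design weight `w_i`. Stems ≥ 12.7 cm diameter are tallied
on a 672.5 m² footprint, stems 2.54–12.7 cm on 54 m², and seedlings
(stems < 2.54 cm above the minimum-length rule) are counted on the 54 m²
footprint. All estimation is restricted to forested plots; non-forested
rows are carried through file round-trips but never enter an estimate.
Records flagged as seedlings are assumed to have passed the minimum-length
rule upstream — lengths are not part of the schema.

## Cohort definitions

Tree age is unmeasured, so size stands in for age. Seedlings are the
tallied recruits; the mature cohort of a species is the set of stems with
diameter at or above the `p`-th percentile (default 0.75; 0.60 and 0.85
for sensitivity) of the species' estimated stand diameter distribution.
Stems between 2.54 cm and the cutoff belong to neither cohort; the gap is
what gives the cohorts temporal separation.

The diameter distribution is estimated from *all* measured stems of the
species on forested plots, each weighted by
`plot weight × count / subplot area`. Expansion weighting is the
design-consistent choice: a microplot stem represents ~12.5× more stems
per unit area than a subplot stem, and the 54/672.5 detection ratio in
the field design exactly offsets the 1/54 vs 1/672.5 expansion, so the
weighted distribution estimates the true stand distribution.

Quantiles (here and everywhere else in the package) use the
left-continuous inverse of the weighted empirical CDF — the smallest data
value `y` with `F(y) ≥ p`. The convention is chosen for determinism and
exact reproducibility; no interpolation, no ties ambiguity.

Species enter the mean-shift analysis if they occur in ≥ 25 plots as
seedlings *and* ≥ 25 as mature trees; the tail (percentile) analysis
requires ≥ 100 of each, because distribution extremes need larger samples
than means. An explicit exclusion list (non-native species, taxa the
inventory cannot resolve) is honored before the count filter.

## Estimators

**Domain means.** The mean attribute of a cohort's range is the domain
ratio estimator `R̂_d = Σ w z y / Σ w z` over forested plots with a
non-missing attribute (plots missing an optional attribute such as
tmin/tmax are skipped for that attribute only, and the count is logged).

**Differences and variance.** The shift is `Δ̂ = R̂_s − R̂_t` with the
Taylor-linearization variance described in the README: per-plot influence
values `u_i` and `var = n/(n−1) Σ u_i²` over the `n` forested plots,
treating the spatially balanced design as with-replacement sampling of
plots. This is the standard conservative approximation; no local
neighborhood variance estimator is attempted. Stratification enters only
through the weights by default; a stratified-sum variance
(`Σ_h n_h/(n_h−1) Σ (u_i − ū_h)²`) is available behind
`stratified_variance=True`. Because both cohort indicators live on the
same plots, the covariance between `R̂_s` and `R̂_t` is carried entirely by
the joint influence values; identical memberships give `Δ̂ = 0` with
`se = 0` exactly. 95% CIs are normal with the quantile fixed at 1.959964.

**Tails.** 5th/95th percentile shifts use the weighted-quantile convention
above; CIs are percentile-method bootstrap (default 2000 replicates)
resampling whole plots with replacement within stratum, keeping both
memberships attached to the plot so the seedling/tree dependence is
preserved. Degenerate resamples with an empty domain are dropped. The CI
is widened, if necessary, to bracket the point estimate.

**Cross-species combination.** Per-species differences share plots, so
the combined estimate is GLS with the influence-based covariance
`Σ̂_jk = n/(n−1) Σ_i u_i^(j) u_i^(k)`, whose diagonal reproduces each
species' linearized variance exactly. With ~40+ species on one plot set
`Σ̂` can be near-singular, so it is shrunk toward its diagonal,
`Σ̂(λ) = (1−λ)Σ̂ + λ·diag Σ̂`, taking the smallest
λ ∈ {0, 0.05, …, 1} that brings the 2-norm condition number below 1e8;
λ and the condition number are reported in every output row. The GLS
system is solved by Cholesky factorization, never an explicit inverse
(tested against the explicit-inverse oracle at 1e-10 relative). A joint
plot-bootstrap covariance (`joint_bootstrap_covariance`) exists as a
sensitivity alternative that makes no delta-method approximation; the
linearization is the default because it is deterministic and orders of
magnitude faster, and the two agree on synthetic data.

Group estimates (angiosperm vs gymnosperm, from a configurable species →
group map) apply the same GLS to the group's subvector and submatrix; a
partition's group estimates need not average to the overall estimate and
no such constraint is imposed.

**Significance reporting.** Per-species significance is at the 0.05 level
with no multiple-testing correction: species are reported estimate-by-
estimate with CIs, and inference rests on the combined estimate. In the
latitude×elevation quadrant summary a difference of exactly 0 counts as
positive (a measure-zero tie-break on continuous data).

## Synthetic generator

The generator emulates exactly the design features the estimators touch:

- **Landscape.** Latitude band 32.5–49° N; temperature exactly linear,
  `mat = t0 − 0.8·(lat − lat_min) − 6.5·elev/1000` (°C, lapse 6.5 °C/km).
  Elevation is an optional north–south trend plus sinusoidal longitude
  ridges plus noise, floored at −86 m. Plots are placed by
  stratified-grid jitter (one plot per equal latitude slice per stratum);
  counts per stratum are proportional to `area fraction / density`, as a
  systematic grid yields, so the weighted plot density is constant across
  the stratum boundary. 90% of plots are forested.
- **Niches.** Species occupy plots independently with probability
  `p_max·exp(−(x−μ)²/2σ²)` on the temperature axis (elevation axis in the
  confounding scenario); the seedling centre is displaced δ toward colder
  conditions. Defaults: 40 species, σ = 2 °C, p_max = 0.8, centres evenly
  spaced on 7–11 °C, δ = 0.12 °C — sample sizes and effect magnitude of
  the same order as a real three-state inventory (≈ 12,000 forested
  plots, per-species domain counts in the hundreds to thousands).
- **Tallies.** Occupied plots carry `1 + Poisson(2)` lognormal-diameter
  stems; stems below 12.7 cm are detected with probability 54/672.5
  relative to large stems, mirroring the nested footprints, so expansion
  weighting downstream is genuinely exercised. Diameter parameters vary
  across species so estimated 75th-percentile cutoffs span ≈ 6–31 cm.
  Seedling counts are `1 + Poisson(rate − 1)` per occupied plot.
- **Truth.** `truth.csv` records each species' exact estimand: the
  occupancy-probability-weighted population mean temperature of each
  cohort, integrated over the generated forested plots. With δ = 0 the
  two cohorts' truths are identical by construction.

**What the generator does not model**, and hence what passing tests do
not establish about real data: spatial autocorrelation of presence
(plots are independent given the environment), dependence between
seedling and tree presence on a plot, demographic dynamics through time,
measurement error in climate attribution, and real topography. A true
spatially balanced (GRTS-style) draw is approximated by grid jitter; the
estimators do not exploit spatial structure, so this suffices for
validating them.

**Niche placement and the estimand.** Gaussian occupancy weighting pulls
cohort means toward the interior of the regional temperature
distribution; where the log-density of temperature is curved, the planted
δ and the population-level difference of cohort means diverge. The
default landscape therefore keeps the temperature density flat across the
niche span (small elevation variance, niche centres ≥ ~1.7σ from the
density shoulders), leaving only a small tail-truncation shrink: the
per-species population difference is ≈ −0.95δ rather than −δ. Validation
therefore distinguishes two targets: *recovery* is judged against the
planted δ (the combined estimate lands within 0.01 °C of it), while *CI
coverage* is judged against the exact per-replicate estimand — the
GLS-weight-averaged truth — since that is what the estimator converges
to.

**Scenarios** (`perturb_scenario`) deform the community to emulate
documented non-climatic mechanisms: `edge_contraction` multiplies
seedling occupancy by a factor < 1 on the warm side of each niche
(abundance shifting toward the cold end without the footprint moving);
`pathogen_patch` multiplies both cohorts' occupancy by a seeded Gaussian
suppression patch; `elevational_confound` re-expresses niches on the
elevation axis through the lapse rate (σ and δ scaled by 1000/6.5 m/°C).
The confound demonstration runs on a landscape whose elevation declines
northward at 123.1 m/° — the slope `1000·lat_gradient/lapse_rate` at
which latitude and elevation exactly trade off in temperature, and close
to the observed decline of timberline elevation with latitude in western
North America — with small ridges, so selecting on elevation moves
species up and *south* while their temperature envelope barely moves.

## Validation experiments and problem sizes

All Monte-Carlo experiments live in `rangeshift.validation`, run on a
lean array path through the same estimator code, and are reproducible
from a single master seed (per-replicate streams are spawned from it).
Sizes were chosen so the full suite runs in minutes on one CPU:

- recovery and coverage: 200 replicates × 12,000 plots × 40 species;
- variance calibration: 200 replicates at 500 plots plus one
  2000-replicate plot bootstrap, single wide-niche species (σ = 3,
  p_max = 0.9, so the two domains hold ~100 plots each at n = 500);
- null control: 30 replicates × 3,000 plots × 40 species = 1,200
  species-level tests;
- confounding: 50 replicates × 6,000 plots × 12 species, δ = 0.3 °C
  (≈ 46 m uphill) so the per-species elevation shift is individually
  detectable at these sample sizes;
- sensitivity: one 12,000-plot dataset re-analysed at cohort percentiles
  0.60/0.75/0.85 with the stem draws frozen, so only the cutoff moves.

No empirical number is stated here that the tests or
`scripts/acceptance.py` do not themselves compute.

## Numerical choices and degenerate inputs

- Weighted quantiles: left-continuous inverse CDF, `searchsorted` on the
  cumulative weights; zero-total-weight and empty inputs raise.
- Ratio estimators: empty domains raise `InsufficientDataError`; fewer
  than 2 universe plots make the variance undefined and raise.
- Influence vectors are stored per estimate (indexed by plot id); the
  covariance builder refuses mismatched plot universes rather than
  silently aligning.
- All estimates are invariant to rescaling every weight by a positive
  constant and equivariant under shifting the attribute; both are
  property-tested.
- CSV output uses pandas' default float repr (shortest round-trip), and
  the run log carries no timestamps, so a fixed seed yields byte-identical
  bundles.

## Known limitations

- The with-replacement variance ignores any variance reduction from
  spatial balance; on a real systematic sample the CIs are mildly
  conservative.
- GLS with an estimated covariance is slightly anticonservative when the
  number of species is large relative to the information per species;
  simulation shows coverage within the nominal band at the default scale.
- The mature-cohort definition inherits whatever diameter measurement
  protocol produced the tallies (e.g. root-collar diameters for
  multi-stem woodland species are not special-cased).
- Temperature is consumed as a plot attribute; constructing it (climate
  surface interpolation) is out of scope.
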