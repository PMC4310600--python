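# rangeshift

Design-based detection of tree-species range shifts from the joint
distribution of seedlings and mature trees on a forest-inventory
probability sample.

## The problem

Tracking a warming climate, tree species are expected to recruit seedlings
in cooler locations than those occupied by their mature trees. Repeated
measurements spanning decades are rarely available, but a single
spatially balanced inventory — thousands of fixed-area plots tallying every
stem by species and size — already contains the signal: the *current*
seedling distribution stands in for future range, the mature-tree
distribution for past recruitment. This package estimates, for every
species, the difference in mean annual temperature (and elevation,
latitude, or temperature extremes) between the range of its seedlings and
the range of its mature trees, with design-based standard errors, and
combines the per-species differences into an overall shift.

It is written for analysts of national-forest-inventory-style data
(plot + tally tables with nested subplot footprints and per-stratum
sampling densities) and for methodologists who want a fully synthetic,
ground-truth-bearing test bed for domain estimation on probability samples.

## The statistics

For plot attribute $y_i$, design weight $w_i$ (km² represented by the
plot), and domain indicator $z_{di}$ (plot hosts the species' cohort $d$),
the mean attribute of the cohort's range is the **domain ratio estimator**

$$\hat R_d = \frac{\sum_i w_i z_{di} y_i}{\sum_i w_i z_{di}},$$

and the range shift is $\hat\Delta = \hat R_s - \hat R_t$ (seedlings minus
mature trees). Its variance comes from **Taylor linearization**: the
per-plot influence values

$$u_i = w_i\Big[\frac{z_{si}(y_i-\hat R_s)}{\hat N_s} - \frac{z_{ti}(y_i-\hat R_t)}{\hat N_t}\Big],\qquad
\widehat{\mathrm{var}} = \tfrac{n}{n-1}\sum_i u_i^2,$$

computed over all $n$ forested plots, so the seedling/tree dependence (a
plot may host both cohorts) is captured without any independence
assumption. Range *boundaries* are compared through left-continuous
weighted empirical quantiles (5th/95th percentiles) with stratified plot
bootstrap CIs. Across species, the overall shift is the **GLS average**
weighted by the inverse of the cross-species covariance matrix
$\Sigma_{jk} = \frac{n}{n-1}\sum_i u_i^{(j)}u_i^{(k)}$ — the species are
estimated from the same plots and are far from independent.

Cohorts are defined by size as a proxy for age: seedlings are stems below
2.54 cm diameter; mature trees are stems at or above the species' 75th
percentile diameter (expansion-weighted across the nested 672.5 m² /
54 m² subplot footprints), with 60th/85th-percentile sensitivity reruns.

Because real inventory plot coordinates are confidential, the package
ships a synthetic-inventory generator (`rangeshift.synthetic`) with
Gaussian thermal niches and a planted seedling shift δ, giving every
estimator an exact, integrable ground truth.

## Worked example

Generate a 4,000-plot inventory of 12 species with a planted 0.12 °C
seedling shift toward colder conditions, then run the full analysis:

```sh
rangeshift simulate --out demo --n-plots 4000 --seed 42 --n-species 12 --delta 0.12
printf 'n_boot: 500\nseed: 7\n' > demo/config.yml
rangeshift run --plots demo/plots.csv --tally demo/tally.csv \
               --config demo/config.yml --out demo/out
```

which prints:

```
group attribute  mean_diff       se    ci_low   ci_high  n_species  lambda  condition_number
  all       mat  -0.153509 0.026302 -0.205060 -0.101959         12     0.0          1.414582
  all elevation   3.944115 1.930338  0.160721  7.727509         12     0.0          1.562904
  all  latitude   0.160668 0.035672  0.090751  0.230584         12     0.0          1.476831
```

Reading: across the 12 species, the seedling ranges average 0.154 °C
**colder** than the mature-tree ranges (95% CI −0.205 to −0.102 — the
planted −0.12 is comfortably inside), about 3.9 m **higher**, and 0.16°
latitude (~18 km) further **north** — the joint signature of a shift
toward cooler conditions. `demo/out/` also contains the per-species table
(`species_shifts.csv`), the latitude×elevation sign-quadrant summary
(`quadrants.csv`), 5th/95th-percentile shifts for well-sampled species
(`percentile_shifts.csv`), the cohort-percentile sensitivity table
(`sensitivity.csv`), and a deterministic `manifest.json` + `run.log`.

The same analysis is available as a library:

```python
import rangeshift as rs

plots, tally = rs.read_inventory("demo/plots.csv", "demo/tally.csv")
result = rs.run_analysis(plots, tally, rs.AnalysisConfig(seed=7))
print(result.combined)
```

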