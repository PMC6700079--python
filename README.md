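# swallowtrace

Tools for linking the African wintering conditions of European-breeding
barn swallows (*Hirundo rustica*) to their subsequent breeding performance.
The package chains four analyses that movement ecologists usually run
separately:

1. **Movement prior** — initial great-circle bearings from breeding to
   winter ringing recaptures are pooled into a von Mises distribution
   (mean direction μ, concentration κ) and rasterized into a prior
   probability surface *f_m* over a sub-Saharan assignment grid.
2. **Multi-isotope assignment** — each feather's (δ²H, δ¹³C, δ¹⁵N) triplet
   is compared with feather isoscapes through a multivariate normal
   likelihood (missing isotopes marginalized out, residual covariance by
   maximum likelihood with an EM step for incomplete triplets). Bayes' rule
   combines it with *f_m* into a posterior origin surface *f_x*; the
   smallest set of highest-posterior pixels holding 67% of the mass becomes
   the individual's binary origin map, and pixels claimed by >50/>60/>70%
   of individuals form nested winter masks with spherical areas in km².
3. **Winter conditions** — mean NDVI over a mask across the twice-monthly
   composites from 1 November (year *i*−1) to 31 March (year *i*), after
   temporal gap filling; ordinary least squares trends on raw calendar year
   (optionally quadratic), stratifiable by biome.
4. **Carry-over path analysis** — piecewise structural equation models per
   sex: winter NDVI, age, their interaction and tail length act on breeding
   date; breeding date on clutch size (females) and fledgling numbers; body
   mass is tied to each reproductive variable by correlated errors. Every
   equation is a Gaussian linear mixed model with crossed random intercepts
   for individual, colony and year (fitted by a fast profiled-ML solver),
   coefficients are standardized path coefficients, goodness of fit is
   Shipley's d-separation test with Fisher's C = −2 Σ ln *p* ~ χ²(2k), and
   indirect effects are products of path coefficients along directed chains.

Because the underlying field data are not publicly archived, a first-class
synthetic-data module generates every input — isoscapes, ringing
recoveries, feather samples, NDVI stacks, and a 30-year longitudinal
breeding table — from a known causal model, so the whole pipeline is
testable end to end. Real rasters (ESRI ASCII grid) and CSV tables enter
through the same interfaces.

## Worked example

The `swallowtrace` command chains the stages on synthetic data:

```sh
cat > sim.yaml <<'YAML'
feathers:
  n: 203
breeding:
  n_individuals: 1000
ndvi:
  years: [1982, 2013]
YAML

swallowtrace simulate --config sim.yaml --out data --seed 3
swallowtrace prior    --recoveries data/recoveries.csv \
                      --grid-template data/isoscape_d2H.asc --out prior
swallowtrace assign   --isoscapes data --feathers data/feathers.csv \
                      --prior prior/prior.asc --out assign
swallowtrace ndvi     --stack data/ndvi --mask assign/mask_gt60.asc \
                      --years 1982:2013 --out ndvi_out
swallowtrace sem      --data data/breeding.csv --sex male --out sem_out
```

The `prior` step prints the fitted bearing distribution:

```
mu = 180.51 deg, kappa = 12.849, n = 253
```

i.e. the 253 simulated recaptures point almost due south of the Danish
breeding centroid, tightly concentrated. `assign` prints the nested winter
masks (areas shrink as the population threshold rises):

```
 threshold  n_pixels     area_km2
       0.5       131 1.102929e+06
       0.6        69 5.803043e+05
       0.7        28 2.351259e+05
```

and `sem` prints the male path analysis — the positive age×NDVI
interaction on breeding date (older males delay breeding after good
winters), the negative effect of breeding date on fledgling numbers, and a
d-separation test consistent with the fitted causal network:

```
     response     predictor  estimate       se            p  conditional_r2
breeding_date           age -3.804443 0.659437 9.206292e-09         0.27296
breeding_date      age_ndvi  3.564808 0.662074 8.126993e-08         0.27296
breeding_date   tail_length -0.127458 0.021323 2.675899e-09         0.27296
breeding_date   winter_ndvi -0.199618 0.067278 3.042043e-03         0.27296
   fledglings           age -0.003965 0.022864 8.623415e-01         0.02223
   fledglings breeding_date -0.149701 0.023035 1.018584e-10         0.02223
   fledglings   tail_length  0.002565 0.022300 9.084553e-01         0.02223
Fisher's C = 4.0, df = 4, p = 0.406
```

Estimates are standardized path coefficients; the indirect effect of the
age×NDVI interaction on fledglings is their product along the chain
(here 3.565 × −0.150 ≈ −0.53).

The same operations are available as library functions
(`swallowtrace.fit_von_mises`, `assign_population`, `winter_series`,
`fit_trend`, `fit_path_model`, …) for programmatic use.

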