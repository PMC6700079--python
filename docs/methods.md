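# Methods

This note records the models behind each pipeline stage, the defaults of
the synthetic-data generator and why they were chosen, the numerical
decisions, and what the test suite does and does not establish.

## Geographic model

All rasters live on regular latitude/longitude grids (pixel centers, row 0
northernmost); the default assignment extent is the sub-Saharan box
15°N–35°S, 17°W–42°E at 0.83° resolution, matching the resolution of the
GIMMS-class NDVI products the NDVI stage emulates. Distances and bearings
use a spherical Earth (R = 6371 km): at sub-degree pixel sizes the
spherical-vs-ellipsoidal bearing difference is orders of magnitude below
the grid resolution. Pixel areas are spherical rectangles,
R²·Δλ·Δφ·cos φ. Rasters are serialized as ESRI ASCII grids — a plain-text
format every GIS reads — with nodata recorded in the header.

## Movement prior

Initial bearings from the breeding centroid (Kraghede, 57.22°N 9.97°E) are
computed at the origin of each great circle. The pooled recovery bearings
get a maximum-likelihood von Mises fit: μ is the circular mean; κ solves
A₁(κ) = R̄ by Brent bracketing on exponentially scaled Bessel ratios, capped
at κ = 500 when bearings are nearly identical (R̄ → 1 leaves κ unbounded).
To rasterize, the bearing from the centroid to every pixel center is
snapped to a 180-node direction grid (1°, 3°, …, 359°; a `snap=False` flag
evaluates the density continuously — the difference is bounded by the
density's Lipschitz constant times 1° and is immaterial at κ below the
cap), the von Mises log-density κ·cos(θ−μ) is evaluated, shifted by its
in-mask maximum before exponentiation (so large κ cannot underflow the
whole surface), and normalized over valid pixels. Normalizing over pixels —
not over the 180 direction nodes — is what makes the prior a probability
surface; a pixel coincident with the centroid, where the bearing is
undefined, receives the mean of its valid neighbours.

## Isotope assignment

The residual covariance of (δ²H, δ¹³C, δ¹⁵N) around isoscape expectations
is estimated by maximum likelihood: closed form (n denominator) for
complete triplets, otherwise EM for the multivariate normal with values
missing at random, iterated until the observed-data log-likelihood improves
by < 1e-8. A near-singular estimate is an error unless an explicit ridge
(ε × mean diagonal, with an absolute fallback when the diagonal itself is
zero) is requested. Per-pixel likelihoods marginalize missing isotopes
(exact under multivariate normality — no imputation); posteriors are
likelihood × prior renormalized, and a likelihood/prior support mismatch is
an error naming the individual. Binarization takes pixels in descending
posterior order (ties broken row-major) until the cumulative mass first
reaches q = 0.67 — a mass-cover rule, not a per-pixel density quantile.
Population thresholds are strict (count/n > p), which is what makes the
>50/>60/>70% masks nested.

**Assignment covariance.** A posterior calibrated to an individual's own
measurement scatter produces a 67% map about as large as the scatter of the
maps themselves, which caps the population overlap near 70% and can leave
the >70% mask empty. Calibration-set covariances in practice are wider:
they absorb isoscape prediction error shared across individuals on top of
individual measurement noise. The pipeline makes that margin explicit — at
assignment time the estimated residual covariance is inflated (default ×2,
i.e. equal parts individual residual and isoscape error; `--cov-inflation`
on the CLI). With the default margin the nested masks are non-empty across
seeds, with areas in the 10⁵–10⁶ km² range.

## Winter NDVI conditions

The winter covariate for year *i* is the unweighted mean over (masked
pixels × composites dated 1 Nov (*i*−1) through 31 Mar (*i*)) — the months
the population spends south of the Sahara — labelled by the January year.
Gap filling is per-pixel linear interpolation in time with nearest-value
extension at the series boundaries and an 8-neighbour-mean fallback; this
deliberately replaces heavier space-time quantile methods because the
covariate is a mask-wide mean over ~150 composites per winter and is
insensitive to the filler at realistic gap rates (the stack records which
filler ran). Trends are OLS with raw (uncentered) calendar year so
coefficients are on the per-year scale; internally the fit uses centered
year and maps coefficients and covariance back through the binomial
expansion, which sidesteps the conditioning of year² ≈ 4×10⁶ without
changing the reported scale. Quadratic fits need ≥ 4 years, linear ≥ 3. A
Durbin–Watson statistic is reported as a diagnostic but p-values do not
adjust for temporal autocorrelation (plain OLS is the documented model).

## Carry-over path analysis

Per sex, the causal network is fitted piecewise, one Gaussian linear mixed
model per endogenous variable, by maximum likelihood (not REML — the
d-separation p-values and the coefficient tests then use the same
likelihood). The female DAG is NDVI, age, age×NDVI, tail → breeding date;
breeding date, age, tail → clutch; clutch, age, tail → fledglings. The male
DAG omits the clutch node (clutch size is the female's trait). Body mass is
linked to each reproductive variable by a correlated-error arc, estimated
as the Pearson correlation of model residuals (mass residualized by OLS on
the exogenous covariates), because the measurement timing leaves the causal
direction unknown.

Crossed random intercepts for ring, colony and year are mandatory in every
sub-model. The solver profiles β and σ² out of the likelihood and optimizes
the variance ratios λ_k = σ²_k/σ² on the log scale; each objective
evaluation reduces the q×q system (I + D Z′Z D) to the largest factor's
diagonal block plus a small dense Schur complement, so a fit at n ≈ 2000
costs milliseconds — what makes the replicate-based calibration suites
affordable. It is cross-checked against statsmodels' MixedLM (ML, variance
components) in the test suite; a variance ratio at the optimizer boundary
is pinned to zero with a warning, never silently dropped. Fixed-effect
p-values are Wald t with n − p residual degrees of freedom; at the sample
sizes targeted here (hundreds to thousands of bird-years) the df convention
is immaterial, and it is recorded in the output. Conditional R² follows the
variance-decomposition convention: (fixed + summed random-intercept
variance) / (those + residual variance).

Variables are z-scored on the listwise-complete analysis set; the age×NDVI
column is the product of the raw variables, z-scored afterwards. Because
age and age×NDVI are strongly collinear when NDVI varies little between
winters, their standardized coefficients are legitimately much larger in
magnitude than the other paths (they offset each other); raw-scale
coefficients are therefore always reported alongside.

The d-separation basis set contains one claim per non-adjacent variable
pair — pairs joined by a directed edge or a correlated-error arc count as
adjacent, exogenous–exogenous pairs are excluded — with the topologically
later variable regressed on the earlier, conditioning on the union of both
variables' parents, using the same random-effects structure. Fisher's
C = −2 Σ ln p is referred to χ² with 2k degrees of freedom (female DAG:
k = 5, df = 10; male DAG: k = 2, df = 4). Indirect effects are products of
standardized path coefficients along a directed chain, conventionally
reported only when every component path is individually significant at
α = 0.05 (two-sided, no multiplicity correction). Prediction surfaces over
an (age, NDVI) grid propagate fixed-effects-only predictions through the
DAG in topological order, back-transform to raw units, and flag (without
refusing) grid points outside the data's covariate hull.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed).

- **Isoscapes**: planar gradient per isotope plus a Gaussian-smoothed
  random field rescaled to a target marginal SD — enough spatial structure
  to make assignment non-trivial, without pretending to reproduce published
  isoscape geometry.
- **Ringing recoveries**: breeding points uniform in the 36–66°N, 5–15°E
  box, bearings from VM(μ = 190°, κ = 4), ranges uniform on 6000–9500 km,
  projected along great circles and rejection-sampled into the winter box
  (bounded retries). Rejection tilts the realized bearing distribution
  toward directions that reach the box — the fitted (μ, κ) describe the
  realized geometry, as they would with real recaptures.
- **Feathers**: isoscape value at a true origin plus correlated
  multivariate normal noise (default SDs 8/2/1.2 ‰ with moderate positive
  correlations), optional per-isotope missingness, never all-missing. The
  default origin region is a 4°×4° box centred due south of the breeding
  site — on the movement-prior ridge, as the recoveries imply.
- **NDVI**: twice-monthly composites = base + linear trend + one annual
  sinusoid + a shared per-year offset (SD 0.015) + white noise, clipped to
  [−1, 1], with missing cells at a set rate. The interannual offset is what
  keeps mask-wide trend fits from being trivially significant: a 32-winter
  series with trend 0.001/yr and year-to-year SD 0.015 gives trend SEs near
  2×10⁻⁴ and moderate R², the regime a real GIMMS-era series occupies.
- **Breeding table**: recruits enter at age 1 in a random year and survive
  each year with probability 0.52 (capped at age 8), reproducing the steep
  age decline of long-term swallow datasets. Breeding date (days from
  1 May — the day-number origin is arbitrary and irrelevant to a linear
  model) follows the causal diagram with a negative main age effect and a
  positive age×NDVI interaction sized so that, at the male mean tail
  length, a yearling moves from day 35 to day 34 and a five-year-old from
  day 21 to day 31 as winter NDVI rises from 0.60 to 0.675; tail length
  costs 0.1 day/mm. Random intercepts (ring 2.5, colony 1.5, year 3.0 days)
  enter the breeding-date equation and reach clutch and fledglings only
  through breeding date, so the causal diagram over observed variables is
  exact. Clutch and fledglings are Gaussian draws rounded and floored at
  zero (fledglings capped at clutch for females), and downstream equations
  consume the observed (rounded) upstream values — this keeps the
  d-separation null calibration exact despite rounding. Body mass is built
  from the reproductive equations' standardized residuals with specified
  correlations (default 0.05 with breeding date, 0 elsewhere).

Passing tests on these data show the estimators recover known generative
structure under Gaussian assumptions with moderate interannual variation;
they do not establish robustness to count-valued reproduction data,
non-random missingness, isoscape misspecification, or observation-driven
sampling effort, none of which the generator emulates.

## Problem sizes used by the checks

The simulation suites run at the scale of the study they emulate: 253
recoveries, ~200 feathers on the 60×71 assignment grid, 32 winters, and
breeding tables of ~2000 bird-years per sex (1000 recruits at survival
0.52). Calibration properties use 100–400 replicates: the d-separation
type-I rate over 200 replicates is checked against the 3–8% band around
the nominal 5%, and sign recovery of the interaction and breeding-date
paths over 100 replicates against a 95% floor.

## Known limitations

- Gaussian sub-models for clutch and fledgling counts (identity link), as
  in the emulated analysis; Poisson/binomial alternatives are out of scope.
- The d-separation basis set treats variables linked only by
  correlated-error arcs as adjacent; no search over alternative DAGs.
- Wald t inference, no Kenward–Roger/Satterthwaite small-sample df.
- The movement prior is direction-only (no range/distance component), and
  one centroid represents the breeding population.
- OLS trend p-values ignore temporal autocorrelation (Durbin–Watson is
  reported for inspection).
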