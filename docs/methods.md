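# Methods

## Assignment model

Each individual carries a two-marker observation y\* = (δ²H_f ‰, wing mm).
The posterior origin probability of grid cell *j* for an individual
breeding at plot *i* is

π_j ∝ N(y\* | μ_j, Σ) · g(d_ij | υ, λ) · N_j,  normalised over the J
in-range cells.

Assumptions worth stating explicitly:

* **Fixed Σ.** The marker covariance is a user input, not re-estimated
  during assignment. The default is the within-site sample covariance of
  the markers ([[47.88, −1.21], [−1.21, 9.20]]), i.e. isotope SD ≈ 6.9 ‰,
  wing SD ≈ 3.0 mm, weak negative correlation. Σ describes *local*
  marker variation around a cell's expectation; all systematic geography
  lives in μ_j.
* **Cell-centre evaluation.** The kernel and likelihood are evaluated at
  cell-centre distance and cell expectation; nothing is integrated over
  the cell's area. At 30 km resolution this is the same approximation the
  basemaps themselves embody.
* **Distance floor.** The Weibull pdf diverges as d → 0 when υ < 1, which
  holds for all three standard priors. Distances are floored at
  `d_floor_km` (default: half the cell size) for kernel evaluation, and
  zero distances are lifted to the same floor before Weibull refitting
  (the Weibull support is positive). A disperser "at distance 0" is in
  truth somewhere within its own cell, so half a cell is the
  resolution-limited minimum. The floor is configurable.
* **Log-space accumulation.** All three factors are summed as log
  densities and normalised with log-sum-exp. On range-wide grids the
  linear-space product underflows; the implementation refuses to return a
  posterior when every cell's log density is −∞ (which indicates a unit
  error, not a numerical nuisance).
* **Marker order.** The (isotope, wing) order is fixed by named columns at
  every interface; positional swapping is the classic silent failure mode
  of multi-marker assignment and is deliberately impossible through the
  public API.

Distances are great-circle on a sphere of radius 6371.0 km. At the spatial
resolution of the method (tens of km) the sphere-vs-ellipsoid difference
(< 0.5 %) is irrelevant.

### Kernel priors

`GAMMA1 = (0.75, 9.26)`, `GAMMA2 = (0.675, 9.78)`, `GAMMA3 = (0.60, 10.47)`
(shape, scale km). All three share a median of λ(ln 2)^(1/υ) ≈ 5.68 km
(reported as 5.7); decreasing shape at fixed median fattens the tail, so
the three span "most restrictive" to "least restrictive" views of
long-distance natal dispersal. The (υ, λ) pairs are taken as authoritative;
the scale values reproduce the 5.7 km figure only to ≈ 0.3 % because 5.7
is itself a rounded number.

## Bootstrap dispersal estimation

Each of B replicates (default 1000) draws one origin cell per individual
from its posterior via the categorical distribution, computes the
dispersal distance, refits a Weibull by maximum likelihood
(`scipy.stats.weibull_min.fit` with location pinned at 0), classifies
long-distance immigrants (D ≥ threshold, boundary inclusive; default
100 km, with 50 and 150 km as sensitivity settings), and summarises
per-plot immigrant counts and rates. Summaries are empirical 2.5/97.5 %
percentiles across replicates ("95 % bootstrap intervals"). Replicates
whose kernel fit fails are flagged, counted, and excluded from quantile
summaries. All draws derive from one root seed through a dedicated
substream, so any replicate is reproducible in isolation.

This bootstrap propagates *assignment* uncertainty (how unsure we are of
each individual's origin), not sampling uncertainty in the set of
individuals; with perfectly sharp posteriors its intervals collapse to a
point. With markers as blurry as real isoscapes the replicate draws are
close to fresh samples from the origin distribution and the intervals
behave like ordinary bootstrap intervals — the transect benchmark below
relies on this.

## Habitat-selection regressions

Immigrant status per individual (per replicate) is regressed on its
plot's covariate with single-predictor logistic models: patch quality R
(self-recruitment rate, the expected population growth rate absent
immigration), habitat amount (ha of forest within 2 km), and conspecific
density (birds/ha) with linear + quadratic terms for the hump predicted
by the social-cues hypothesis. Multi-predictor mixed models are excluded
by design: with 12 plots the random-effect variances are not estimable.

Covariates enter in raw units (a `standardize` flag exists for
robustness checks); the optimiser internally rescales the column by its
maximum absolute value for conditioning and back-transforms the
coefficients, so reported effects are per raw unit. Replicates with
complete or quasi-complete separation (|scaled coefficient| > 50, a
failed Newton step, or a single-class response) are excluded with a
logged count; a summary built from fewer than half the replicates carries
a warning flag. Across-replicate means, 2.5/97.5 % percentiles and the
proportions of slopes above/below zero (one-tailed sign probabilities)
are reported for every coefficient; the predicted directions are
quality +, habitat +, density linear +, density quadratic −, but both
tails are always reported.

Whether density should enter raw or centred is genuinely open; raw is
the default here, and because a single-predictor logistic model is
invariant to affine reparameterisation of x only jointly (linear and
quadratic coefficients mix under centring), sign probabilities of the
quadratic term are unaffected while the linear term's meaning changes —
users comparing to centred analyses should refit with centred x rather
than transform coefficients.

## Synthetic data generator

`synthetic.Scenario` specifies a rectangular grid (cell size km),
latitudinally graded expected isotope and wing surfaces (per-km slopes,
optional iid per-cell surface noise), a uniform or lognormal-random
abundance field, a true Weibull kernel, a true Σ, plots with covariates,
and per-plot sample sizes. Origins are drawn from the discrete
distribution ∝ kernel(d) · N_j over cells — exactly the generative model
the assignment posterior inverts — and observed markers are bivariate
normal around the origin cell's expectation. One root seed feeds named
substreams (basemap, origins, markers, immigration) so components are
independently reproducible.

Defaults are chosen to emulate the study system: 30 km cells, 12 plots
whose covariates and per-plot sample sizes are the packaged observed
table (506 individuals), isotope gradient −0.02 ‰/km (≈ −2.2 ‰ per degree
latitude, a typical eastern-North-American growing-season gradient after
feather calibration), wing gradient +0.0075 mm/km (≈ 15 mm across a
2000 km range), and the default Σ. With these values the markers localise
an origin only to a few hundred km — deliberately so, since that is the
resolution real feather-isotope assignments achieve.

What the generator does *not* emulate: spatially correlated isoscape
error (cell noise is iid), elevational isotope structure, inter-annual
marker drift, sex/age marker differences, and observation error in the
plot covariates. Passing recovery tests therefore demonstrate the
estimator's correctness under its own assumptions, not robustness to
basemap misspecification.

### Transect recovery benchmark

End-to-end parameter recovery is benchmarked on a single-column
latitudinal transect of 161 × 2.5 km cells with one central plot,
uniform abundance, true kernel (1.24, 32.24) and the default Σ and
gradients (`synthetic.transect_scenario`). Two deliberate choices:

* **Geometry.** On a full 2-D grid the number of cells at distance d
  grows ∝ d, so the distance distribution implied by "origin ∝
  kernel × abundance" is d·g(d), not g(d); a Weibull refit then converges
  to a biased pseudo-truth and no sample size fixes it. On a transect the
  cell multiplicity per distance band is constant, the implied distance
  distribution is the discretised kernel itself, and the generating
  parameters are the correct recovery target (residual discretisation
  bias at 2.5 km cells is < 1 % of either parameter). The 2-D study-like
  scenario remains the default for pipeline demonstrations, where this
  geometric inflation of apparent dispersal is a real feature of the
  method, visible in the worked example.
* **Kernel.** The benchmark uses shape 1.24 / scale 32.24 (median 24 km)
  rather than a 5.7 km-median prior kernel, because a sub-cell median at
  the native 30 km resolution would measure discretisation, not
  estimation.

At 300 individuals and B = 200 the 95 % bootstrap interval covers both
true parameters in ≥ 80 % of 20 independent repetitions (asserted in the
acceptance suite).

### Immigration-effect generator

For regression recovery the per-plot immigration probability follows
logit p = −4 + 6·density − 3·density², a hump peaking at 1 bird/ha with
plot probabilities ≈ 0.10–0.27 — the same order as observed long-distance
immigration rates (1–21 % depending on prior). Habitat and quality
coefficients default to 0. Note that flags generated from this model are
*not* independent of habitat amount, because density and habitat are
correlated across plots; null-calibration checks therefore use an
intercept-only generator (constant p ≈ 0.2), under which the habitat sign
probability is ~0.5 by construction.

## Numerical choices and problem sizes

* Weibull MLE: `weibull_min.fit(floc=0)`; fits failing to produce finite
  positive parameters are treated as non-converged replicates.
* Logistic MLE: Newton iterations (statsmodels `Logit`), max 200
  iterations, on the max-abs-scaled covariate.
* Posterior normalisation: `scipy.special.logsumexp`; posterior rows are
  validated to sum to 1 within 1e-6 before categorical draws, and
  abundance inputs to 1 within 1e-9.
* Test and benchmark sizes (chosen to exercise the asymptotics the
  checks rely on while staying desk-scale): 10⁵ draws for categorical
  calibration and large-n Weibull recovery; 20 × (300 individuals,
  B = 200) for transect coverage; B = 200 replicate flag sets of 506
  individuals for regression recovery; B = 1000 remains the pipeline
  default.

## Known limitations

* The abundance and kernel priors act on cells, not on distance bands;
  as discussed above this makes "dispersal distance" estimates on 2-D
  ranges systematically longer-tailed than the kernel prior — a property
  of the assignment framework itself, reproduced faithfully here.
* Basemaps are accepted as flat CSV layers only; georeferenced raster
  ingestion and reprojection are out of scope, as are kriging/isoscape
  modelling from point data.
* Two markers are assumed throughout (the likelihood uses the closed-form
  2×2 inverse); extending to more markers means swapping in a Cholesky
  solve and widening the named-column interfaces.
* No model selection across kernel families (lognormal, Cauchy-tailed
  kernels are not implemented), and no spatial autocorrelation among
  plots in the regressions.
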