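# isoassign

Bayesian multi-marker assignment of natal origins, dispersal-kernel
estimation, and habitat-selection hypothesis tests for movement ecology.

`isoassign` is aimed at researchers who infer where individual animals were
born from *intrinsic markers* — tissue values that record the geography of
the natal site, such as feather stable-hydrogen isotope ratios (δ²H_f, ‰)
and geographically graded morphometrics (wing chord, mm). Given gridded
basemaps of expected marker values over a breeding range, the package
estimates a posterior origin surface per individual, converts it into
bootstrap distributions of natal dispersal distance, classifies
long-distance immigrants, and tests which patch characteristics (habitat
amount, patch quality, conspecific density) drive long-distance
immigration.

## The model

For individual *k* breeding at plot *i* with observed marker vector
y\* = (δ²H_f, W), the posterior probability that grid cell *j* was its
natal origin is

```
π_j  ∝  N(y* | μ_j, Σ)  ·  g(d_ij | υ, λ)  ·  N_j
```

* **Marker likelihood** — bivariate normal around the cell's expected
  marker vector μ_j with a fixed residual covariance Σ (default: the
  within-site sample covariance `[[47.88, −1.21], [−1.21, 9.20]]` for
  (isotope ‰, wing mm)). Computed in log space and normalised by
  log-sum-exp over cells.
* **Dispersal-kernel prior** — a Weibull density g with shape υ and scale
  λ (km) evaluated at the great-circle plot-to-cell distance. Three
  standard priors `GAMMA1=(0.75, 9.26)`, `GAMMA2=(0.675, 9.78)`,
  `GAMMA3=(0.60, 10.47)` share a ~5.7 km median but admit increasing
  long-distance dispersal. Distances are floored at half a cell because
  the Weibull pdf diverges at 0 for υ < 1.
* **Abundance prior** — N_j, the cell's share of range-wide breeding
  abundance.

Uncertainty propagates by bootstrap: each of B replicates draws one origin
cell per individual from `categorical(π_k)`, yielding dispersal distances
D_k; a Weibull is refit by maximum likelihood per replicate; individuals
with D_k ≥ 100 km (sensitivity: 50/150 km) are classified as long-distance
immigrants; and per-replicate logistic regressions of immigrant status on
plot covariates give percentile intervals and one-tailed sign
probabilities that discriminate the random, ideal-free, ideal-dominance
and social-cues habitat-selection hypotheses.

## Worked example

Simulate a study-like system (12 plots, 506 individuals, 20×20 grid of
30 km cells, the packaged plot covariates) and fit it under the most
restrictive prior:

```python
from dataclasses import replace
from isoassign import DispersalModel, GAMMA1
from isoassign.synthetic import study_scenario, make_basemap, simulate_individuals

scn, plots = study_scenario(seed=1)
scn = replace(scn, n_lon=20, n_lat=20)
basemap = make_basemap(scn)
individuals, truth = simulate_individuals(scn, basemap, plots)

model = DispersalModel(individuals, basemap, plots, prior=GAMMA1)
res = model.fit(n_boot=200, seed=1)
print(res.summary())
```

```
Natal dispersal assignment: bootstrap results
========================================================
individuals: 506   cells: 400   plots: 12
prior kernel: Gamma1 (shape 0.75, scale 9.26 km, median 5.7 km)
bootstrap replicates: 200 (seed 1)

Fitted dispersal kernel (mean [95% bootstrap interval]):
  shape            1.54  [1.44, 1.66]
  scale (km)      40.73  [38.65, 43.57]
  median (km)     32.10  [30.42, 33.83]

Long-distance immigrants (threshold 100 km):
  plot    n   median [95% CI]   rate
  1       82     2.0 [0.0, 6.0]   0.031
  2       80     3.0 [0.0, 6.0]   0.033
  ...
```

The refit kernel implies a ~32 km median dispersal distance — far beyond
the 5.7 km prior median — because on a two-dimensional grid the number of
candidate cells grows with distance, and marker blur spreads posterior
mass accordingly; the per-plot tables report the median number of
long-distance immigrants with bootstrap 95% intervals. Habitat-selection
tests follow from the same fit:

```python
res.selection_tests()            # R, habitat_ha, density + density² effects
res.regress("density", quadratic=True).sign_probability("density", +1)
```

A command-line interface wraps the same pipeline:

```bash
isoassign simulate --outdir demo --seed 8
isoassign all --basemap demo/basemap.csv --individuals demo/individuals.csv \
    --plots demo/plots.csv --outdir demo/results --n-boot 200 --seed 8
```

`demo/results/` then holds per-replicate kernel fits, immigrant tables per
prior and threshold, regression summaries, and a `manifest.json` with the
config hash and output checksums (identical config + seed reproduces
byte-identical outputs).

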