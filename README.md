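# herbiscape

Hierarchical spatial modelling of camera-trap counts for unmarked wildlife
populations, and the synthesis of multi-species density surfaces into
landscape-scale herbivory regimes ("herbiscapes").

The package is aimed at ecologists analysing grid-based camera-trap
surveys: it estimates how intensively each species *uses* every cell of a
landscape grid (relative density, not absolute abundance), separates that
ecological signal from the detection process at camera sites, maps the
leftover spatial structure, and then clusters the landscape by the
biomass and functional composition of the herbivore community. A
vegetation module links the resulting regimes to tree-sapling browsing
outcomes.

## The model

Counts `y_i` at camera site `i` (nested in grid cell `j[i]`, running for
`d_i` days) follow an N-mixture model with Poisson detections:

```
y_i | N_j[i] ~ Poisson(N_j[i] · γ_i · d_i)
N_j          ~ NegBin(mean λ_j, dispersion φ)        Var N = λ + λ²/φ
log λ_j      = x'_λj β_λ + ω_j                       (landscape scale)
log γ_i      = x'_γi β_γ + ε_i,   ε_i ~ N(0, σ²)     (site scale)
```

`ω = K δ` is a Restricted Spatial Regression (RSR) random effect: `K`
holds the leading Moran eigenvectors of the grid adjacency projected
orthogonal to the fixed-effect design, so the smooth spatial term cannot
absorb covariate effects. The latent abundances `N_j` are marginalised by
a finite sum to `N_max = 100` ("integrated likelihood"), and the posterior
is sampled with blocked adaptive Metropolis-Hastings (3 chains, Gelman–
Rubin diagnostics, posterior-predictive Bayesian p-value).

Downstream, per-species density surfaces are converted to biomass
(kg/cell), community functional dispersion (FDis, Gower traits +
abundance-weighted centroid) is mapped, and cells are clustered by
hierarchical clustering on principal components (Ward/Euclidean, optional
k-means consolidation) into `k` herbiscapes.

A full synthetic-data generator reproduces the statistical structure the
model assumes (smoothed standardized covariate rasters, NegBin latent
fields, Poisson camera counts with lognormal site noise and effort
offsets, planted community regimes, browsing outcomes per regime), so the
entire pipeline is testable without field data.

## Worked example

```python
import numpy as np
from herbiscape import (SimulationConfig, CameraPlan, simulate_dataset,
                        SpatialAbundanceModel, posterior_predictive_pvalue)

config = SimulationConfig(
    n_x=20, n_y=20,                      # 400 cells, 500 m side
    beta_lambda=(0.5, 0.8, -0.4),        # intercept, openness, canopy height
    phi=2.0, sigma=0.3,
    camera_plan=CameraPlan(n_sites=150, effort_range=(20, 40)),
    seed=100,
)
grid, latent, survey, _ = simulate_dataset(config)

model = SpatialAbundanceModel(n_iter=20_000, n_burn=10_000, thin=10,
                              n_chains=3, basis_rank=20, random_state=500)
model.fit(survey, grid)

print(model.summary_.round(3))
print("max R-hat (beta):", round(model.rhat_.filter(like="beta").max(), 3))
print("Bayesian p-value:", posterior_predictive_pvalue(model, seed=1, max_draws=100))
```

Output (about two minutes on one CPU):

```
                             mean     sd  q0.025  q0.975  differs_from_zero
parameter
beta_lambda[intercept]      0.460  0.166   0.135   0.796               True
beta_lambda[openness]       0.819  0.143   0.550   1.117               True
beta_lambda[canopy_height] -0.473  0.122  -0.712  -0.235               True
beta_gamma[intercept]      -1.032  0.121  -1.285  -0.798               True
phi                         4.033  4.141   1.192  15.587               True
sigma                       0.282  0.084   0.133   0.456               True
tau                         4.289  4.107   0.575  15.675               True
max R-hat (beta): 1.012
Bayesian p-value: 0.47
```

Every landscape coefficient recovers its true value (0.5, 0.8, −0.4)
well within its 95% credibility interval; the chains agree (R-hat ≈ 1)
and the posterior-predictive p-value near 0.5 indicates the replicated
data look like the observed data. `model.samples_` holds the thinned
draws; `herbiscape.predict` turns them into density surfaces, spatial
residual maps, effect curves and ranked-density curves, and
`herbiscape.community` / `herbiscape.vegetation` carry the community and
browsing analyses.

The same flow is available from the shell:

```bash
herbiscape run-all --seed 1 --outdir demo_run          # staged pipeline
herbiscape run-all --profile full ...                  # full-length MCMC
```

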