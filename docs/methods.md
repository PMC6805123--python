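# Methods

## Model

Camera-trap counts are modelled at two nested scales. Each camera site
`i` runs `d_i` days inside one cell `j[i]` of a regular grid (default
cell side 500 m, 25 ha). Counts are Poisson with intensity
`N_j γ_i d_i`: `N_j` is the number of individuals *using* cell `j`
during the study (a relative density — sites are much closer together
than the species' home ranges, so cells share individuals and `N` must
not be read as absolute abundance), `γ_i` is the expected detections per
individual per day at site `i`, and `d_i` is the effort offset. `N_j` is
Negative-Binomial with mean `λ_j` and dispersion `φ`
(`Var = λ + λ²/φ`), absorbing extra-Poisson variation between cells.
Both scales carry log-linear regressions: `log λ_j = x'_λj β_λ + ω_j`
and `log γ_i = x'_γi β_γ + ε_i` with lognormal site errors
`ε_i ~ N(0, σ²)`. Covariates are standardized (mean 0, SD 1); selected
covariates also enter squared, allowing interior optima. The λ-predictor
carries the ecology; the γ-predictor soaks up finer-scale selection,
activity and observation effects, including season through site-level
weather covariates when provided.

Closure is assumed (no distributional change during the survey) and
species are fitted independently.

### Spatial random effects (RSR)

`ω` follows a Restricted Spatial Regression prior: with rook adjacency
`A` (queen available) and ICAR precision `Q = diag(A1) − A`, the Moran
operator `P⊥ A P⊥` (where `P⊥` projects orthogonally to the columns of
`X_λ`) is eigendecomposed and the top `q` eigenvectors form the basis
`K`. Then `ω = Kδ` with `δ ~ N(0, (τ K'QK)⁻¹)` and `τ ~ Gamma(0.1,
0.1)`. Because `K'X_λ = 0` by construction, the spatial term cannot
alias covariate effects (the confounding that plagues unrestricted CAR
models), and the reduced rank (default `q = min(⌈0.1 G⌉, #positive
eigenvalues)`) keeps computation light. The deliberately informative
Gamma(0.1, 0.1) prior on τ reflects that variance components in these
models are weakly identified and that covariates are not expected to
absorb all spatial dependence.

### Priors

Regression coefficients: Normal with precision 1e-3 (SD ≈ 31.6,
diffuse). Site-error SD: σ ~ Uniform(0, 100). RSR precision:
τ ~ Gamma(0.1, 0.1) (shape, rate). NegBin dispersion: φ ~ Gamma(0.1,
0.1), configurable — a vague positive prior in keeping with the others.
Out-of-support states yield a −inf log-posterior (sampler rejection),
never an exception.

### Integrated likelihood

The discrete latent `N_j` is summed out up to `N_max = 100` individuals
per cell; the NegBin prior is *not* renormalized after truncation
(matching the finite-sum device the model was designed with — at the
default scales the omitted tail is < 1e-12 and tests confirm the
log-likelihood is insensitive to raising `N_max`). The Poisson factors of
all sites in a cell enter the sum only through the sufficient statistics
`Y_j = Σ y_i`, `R_j = Σ γ_i d_i` and `Σ y_i log(γ_i d_i)`, so one
likelihood evaluation is a single `(N_max+1) × (#occupied cells)`
log-sum-exp — numerically stable for counts ≤ 1e4 and fast enough for
full MCMC on a laptop. Cells without cameras carry no data and
contribute exactly zero.

## Sampler

Blocked Metropolis-Hastings, deterministic given a seed:

* one adaptive-covariance block over `(β_λ, β_γ)` jointly — the
  abundance and detection intercepts sit on a weakly identified ridge
  (only their sum is strongly constrained by the data; the NegBin
  discreteness and within-cell camera replication identify the split),
  and a joint block learns that geometry;
* one adaptive-covariance block for `δ`;
* all `ε_i` simultaneously by per-cell Metropolis: given the other
  parameters the cells are conditionally independent, so a joint
  proposal for the sites of each cell can be accepted or rejected cell
  by cell in one vectorised pass;
* random-walk scalars for `φ`, `σ`, `τ` (the latter two need no
  likelihood evaluation).

Scales adapt by Robbins-Monro toward 0.35 acceptance (0.25 for blocks,
with Haario-style empirical covariance); all adaptation happens during
burn-in and is frozen afterwards, so the post-burn-in kernel satisfies
detailed balance. Initialization: `β` from a Poisson GLM that ignores
the latent layer (log-effort offset), `ε = δ = 0`, `φ = τ = σ = 1`,
jittered per chain for overdispersed starts. A NaN log-posterior aborts
with a diagnostic (−inf is the mechanism for out-of-support states).

Desk-scale defaults are 3 chains × 20,000 iterations (burn-in 10,000,
thinning 10); the full-length study settings (3 × 500,000 / 400,000 /
20) are one configuration flag away (`profile: full` in the pipeline).

Convergence is summarized by the classic Gelman–Rubin potential scale
reduction `R̂ = sqrt(((n−1)/n·W + B/n)/W)`. Note this estimator equals
`sqrt((n−1)/n)` — marginally *below* one — when chains coincide exactly;
it approaches 1 from above under real between-chain disagreement.
Goodness of fit uses the posterior-predictive Bayesian p-value with a
chi-square-type discrepancy `Σ (y − E[y])²/E[y]`, `E[y_i] = λ_j[i] γ_i
d_i`; replicates draw `N` then `y` per retained draw, and ties count
toward the replicate (`≥`).

## Synthetic data

The generator draws from exactly the model's assumed distributions, so
passing tests demonstrate internal consistency, not robustness to real
data:

* covariate rasters are Gaussian-kernel-smoothed white noise,
  standardized per layer; the kernel SD (in cells) is the
  autocorrelation knob (real GIS layers would replace these);
* latent abundance is drawn as a Poisson-Gamma mixture (exact NegBin,
  stable in the near-Poisson limit);
* cameras are placed uniformly among cells with a configurable per-cell
  cap (sub-cell geometry, e.g. minimum spacing rules, is irrelevant at
  cell scale), with integer-uniform effort days;
* site covariates are independent standard normals;
* planted community structure: `k` contiguous regimes (nearest of `k`
  seed cells) with regime-specific per-species log-density levels plus
  smooth lognormal noise;
* vegetation plots draw Poisson sapling counts in two height classes
  and Bernoulli browsing flags with regime-specific probability.

Not emulated: real covariate collinearity structure, camera failures,
animal movement, observer misclassification, temporal nonstationarity.
The default trait table carries the six-species ungulate roster with
literature body masses (90/150/20/80/200/400 kg for red deer female/male,
roe deer, wild boar, moose, European bison); its gut- and diet-type
categories are synthetic placeholders consistent with general ungulate
biology.

## Community synthesis

Biomass per cell is `w_s λ_sj` with body-mass weights; totals are exact
sums. Spatial overlap is the Pearson correlation of density surfaces
(constant surfaces yield flagged NaN entries). FDis uses Gower
dissimilarity (range-normalized quantitative traits, 0/1 categorical
mismatch, equal weights), embedded by principal coordinates — with a
Cailliez correction if any eigenvalue < −1e-8, keeping centroid geometry
exact — then the abundance-weighted mean distance to the
abundance-weighted centroid. Herbiscape clustering (HCPC) standardizes
the feature table (species biomasses, total biomass, FDis), projects on
all principal components, builds a Ward/Euclidean tree on the scores,
cuts at `k` (default 5; the inertia-gain curve per candidate cut guides
the choice) and by default consolidates with k-means seeded from the
cluster centroids (off switch for exact-tree reproducibility). Labels
are relabelled contiguously 1..k in order of first appearance, making
partitions permutation-stable.

## Vegetation analysis

Browsing intensity is the proportion of browsed individuals among
≥30 cm saplings per plot (plots with an empty ≥30 cm class are missing
and excluded from fits); recruitment shift is the difference of a focal
species' proportional share between the ≥30 cm and <30 cm classes
(defaults: *Carpinus* and *Acer*, tolerant vs sensitive indicators).
Both are modelled by unweighted OLS with full herbiscape × reserve
interaction; factor levels that collapse to a single value degrade
gracefully to the reduced design, and empty factor combinations are
flagged rather than predicted. Proportions are fitted untransformed
(simple linear models, by design).

## Numerical and design choices

* Event collapsing: within a site × species stream a detection opens a
  new event only when the gap is *strictly* greater than the interval
  (default 5 min) — "independence interval" read as a minimum
  separation, so exact ties merge. Streams of different species never
  merge; input order is irrelevant.
* Standardization uses the population SD (divisor n), recorded so the
  identical transform applies at prediction time; either convention is
  configurable.
* The collinearity screen reports pairs with |r| ≥ 0.7 (absolute value —
  the conservative reading of a correlation ceiling).
* The RSR basis is re-projected once through `P⊥` after the
  eigendecomposition to pin `K'X` at numerical zero (≤1e-12 change to
  the eigenvectors).
* Posterior point surfaces default to the posterior mean (medians
  configurable); predator-risk layers exported to prey models are
  posterior-mean λ surfaces standardized like any covariate.
* Rasters are written as minimal GeoTIFFs (tifffile with
  ModelPixelScale/ModelTiepoint tags), one band per layer, north-up.

## Problem sizes and limitations

The package's own verification runs at deliberate desk scales: recovery
and calibration studies use 400 cells, 150 cameras, 3 chains × 20,000
iterations and a rank-20 basis, with five replicate simulations for
coverage counts; clustering fidelity uses a 40 × 40 grid with five
planted regimes. These sizes give stable Monte-Carlo behaviour while a
full study-scale run (thousands of cells, 500,000 iterations) remains a
configuration change, not a code change.

Known limitations: intercept pairs across the two scales are only weakly
identified (wide, correlated posteriors are expected; slopes are well
identified); `φ` and `τ` posteriors are diffuse at these data sizes; the
sampler is random-walk based, so very high-dimensional bases (`q` in the
hundreds) will mix slowly; no open-population dynamics, no joint
multi-species likelihood, and no gradient-based samplers.
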