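"""Synthetic data with the statistical structure the model assumes.

Every generator is deterministic for a fixed seed and, unless a
misspecification option is set, draws from exactly the distributions of the
hierarchical model: spatially autocorrelated standardized covariates on a
regular grid, Negative-Binomial latent cell abundance with log-linear
covariate effects plus a smooth spatial residual, and Poisson camera counts
with lognormal site-level detection noise and an effort-day offset.
Community structure for end-to-end tests is planted as contiguous regions
("regimes") with distinct per-species abundance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .abundance import CameraSurvey
from .grid import LandscapeGrid

__all__ = [
    "CovariateSpec",
    "CameraPlan",
    "SimulationConfig",
    "generate_landscape",
    "simulate_latent_abundance",
    "simulate_camera_survey",
    "simulate_trait_table",
    "simulate_community_landscape",
    "simulate_vegetation_plots",
    "DEFAULT_SPECIES",
    "DEFAULT_BIOMASS_KG",
]

# Mean body masses (kg) of the six ungulate classes of the motivating
# Bialowieza system; red deer sexes are kept separate because their masses
# (and hence biomass contributions) differ strongly.
DEFAULT_BIOMASS_KG: dict[str, float] = {
    "red_deer_female": 90.0,
    "red_deer_male": 150.0,
    "roe_deer": 20.0,
    "wild_boar": 80.0,
    "moose": 200.0,
    "european_bison": 400.0,
}
DEFAULT_SPECIES = list(DEFAULT_BIOMASS_KG)

# Gut and diet categories are synthetic defaults consistent with general
# ungulate biology (the study's appendix trait table is not reproduced here).
_DEFAULT_GUT = {
    "red_deer_female": "ruminant",
    "red_deer_male": "ruminant",
    "roe_deer": "ruminant",
    "wild_boar": "monogastric",
    "moose": "ruminant",
    "european_bison": "ruminant",
}
_DEFAULT_DIET = {
    "red_deer_female": "mixed_feeder",
    "red_deer_male": "mixed_feeder",
    "roe_deer": "browser",
    "wild_boar": "omnivore",
    "moose": "browser",
    "european_bison": "grazer",
}
GUT_TYPES = ("ruminant", "monogastric")
DIET_TYPES = ("browser", "grazer", "mixed_feeder", "omnivore")


@dataclass
class CovariateSpec:
    """One landscape covariate layer: Gaussian-smoothed white noise.

    ``smoothing_cells`` is the kernel SD in cell units (0 = pure white
    noise) and controls spatial autocorrelation; ``quadratic`` marks the
    covariate for a squared term in the abundance design.
    """

    name: str
    smoothing_cells: float = 0.0
    quadratic: bool = False


@dataclass
class CameraPlan:
    """Where and how long cameras run: ``n_sites`` cameras placed uniformly
    among cells (at most ``max_per_cell`` each), running for an
    integer-uniform number of days in ``effort_range``."""

    n_sites: int = 150
    effort_range: tuple[float, float] = (20.0, 40.0)
    max_per_cell: int = 3

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one camera site")
        if self.effort_range[0] < 1:
            raise ValueError("effort must be at least 1 day")
        if self.max_per_cell < 1:
            raise ValueError("max_per_cell must be >= 1")


@dataclass
class SimulationConfig:
    """True-parameter counterparts of the model unknowns plus layout.

    ``beta_lambda`` includes the intercept as its first element and must
    have one further entry per covariate (plus one per quadratic flag, in
    spec order).  ``spatial_sd`` is the marginal SD of the smooth spatial
    residual added to log lambda (0 disables it).
    """

    n_x: int = 20
    n_y: int = 20
    cell_size: float = 500.0
    covariates: list[CovariateSpec] = field(
        default_factory=lambda: [
            CovariateSpec("openness", 3.0, quadratic=False),
            CovariateSpec("canopy_height", 3.0, quadratic=False),
        ]
    )
    beta_lambda: tuple[float, ...] = (0.5, 0.8, -0.4)
    beta_gamma: tuple[float, ...] = (-1.0,)
    gamma_covariates: tuple[str, ...] = ()
    phi: float = 2.0
    sigma: float = 0.3
    spatial_sd: float = 0.0
    spatial_smoothing_cells: float = 4.0
    camera_plan: CameraPlan = field(default_factory=CameraPlan)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_x * self.n_y < 4:
            raise ValueError("grid must contain at least 4 cells")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        n_quad = sum(c.quadratic for c in self.covariates)
        expected = 1 + len(self.covariates) + n_quad
        if len(self.beta_lambda) != expected:
            raise ValueError(
                f"beta_lambda needs {expected} entries (intercept + covariates"
                f" + quadratics), got {len(self.beta_lambda)}"
            )
        if len(self.beta_gamma) != 1 + len(self.gamma_covariates):
            raise ValueError("beta_gamma needs 1 + len(gamma_covariates) entries")


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _smooth_field(
    shape: tuple[int, int], smoothing: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (population SD)."""
    field_ = rng.standard_normal(shape)
    if smoothing > 0:
        field_ = gaussian_filter(field_, sigma=smoothing, mode="reflect")
    field_ = field_ - field_.mean()
    sd = field_.std()
    if sd == 0:
        raise ValueError("degenerate constant field")
    return field_ / sd


def generate_landscape(config: SimulationConfig) -> LandscapeGrid:
    """Covariate rasters by kernel-smoothing seeded white noise.

    Each layer is standardized to mean 0 / SD 1 (population convention)
    over the grid; larger ``smoothing_cells`` yields stronger positive
    spatial autocorrelation.
    """
    names = [c.name for c in config.covariates]
    if len(set(names)) != len(names):
        raise ValueError("duplicate covariate names")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
    )
    layers = {
        c.name: _smooth_field((config.n_y, config.n_x), c.smoothing_cells, rng).ravel()
        for c in config.covariates
    }
    return LandscapeGrid(
        n_x=config.n_x, n_y=config.n_y, cell_size=config.cell_size, covariates=layers
    )


def spatial_residual_field(config: SimulationConfig, seed=None) -> np.ndarray:
    """Smooth mean-zero residual for log lambda with SD ``spatial_sd``."""
    if config.spatial_sd == 0:
        return np.zeros(config.n_x * config.n_y)
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    f = _smooth_field((config.n_y, config.n_x), config.spatial_smoothing_cells, rng)
    return config.spatial_sd * f.ravel()


def _lambda_design(grid: LandscapeGrid, config: SimulationConfig) -> np.ndarray:
    cols = [np.ones(grid.n_cells)]
    for c in config.covariates:
        cols.append(grid.covariates[c.name])
    for c in config.covariates:
        if c.quadratic:
            cols.append(grid.covariates[c.name] ** 2)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# latent abundance and camera survey
# ---------------------------------------------------------------------------

def simulate_latent_abundance(
    grid: LandscapeGrid,
    beta_lambda: np.ndarray,
    omega: np.ndarray,
    phi: float,
    seed=None,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Per-cell latent abundance N_j ~ NegBin(mean lambda_j, dispersion phi)
    with log lambda_j = x_j' beta + omega_j.

    Drawn as a Poisson-Gamma mixture, which is exact and numerically robust
    for any dispersion (including the near-Poisson limit phi -> inf).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if config is None:
        config = SimulationConfig(
            n_x=grid.n_x,
            n_y=grid.n_y,
            covariates=[CovariateSpec(n) for n in grid.covariates],
            beta_lambda=tuple(np.asarray(beta_lambda, float)),
        )
    x = _lambda_design(grid, config)
    beta = np.asarray(beta_lambda, dtype=float)
    if beta.size != x.shape[1]:
        raise ValueError(
            f"beta_lambda has {beta.size} entries but the design has {x.shape[1]} columns"
        )
    omega = np.zeros(grid.n_cells) if omega is None else np.asarray(omega, float)
    if omega.size != grid.n_cells:
        raise ValueError("omega must have one entry per cell")
    lam = np.exp(x @ beta + omega)
    rng = np.random.default_rng(seed)
    return rng.poisson(rng.gamma(phi, lam / phi))


def simulate_camera_survey(
    grid: LandscapeGrid,
    latent_n: np.ndarray,
    camera_plan: CameraPlan,
    beta_gamma: np.ndarray,
    sigma: float,
    seed=None,
    gamma_covariates: tuple[str, ...] = (),
) -> CameraSurvey:
    """Camera sites, effort and Poisson counts given the latent abundance.

    gamma_i = exp(x_gamma_i' beta_gamma + eps_i) with eps_i ~ Normal(0,
    sigma^2); counts y_i ~ Poisson(N_j[i] * gamma_i * d_i).  Site covariates
    are drawn independently standard normal (they are standardized inputs in
    the fitted model).
    """
    latent_n = np.asarray(latent_n)
    if latent_n.size != grid.n_cells:
        raise ValueError("latent abundance must have one entry per cell")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    plan = camera_plan
    # uniform placement with a per-cell cap
    slots = np.repeat(np.arange(grid.n_cells), plan.max_per_cell)
    if plan.n_sites > slots.size:
        raise ValueError("more cameras than available cell slots")
    cells = rng.permutation(slots)[: plan.n_sites]
    cells.sort()
    lo, hi = plan.effort_range
    effort = (
        np.full(plan.n_sites, float(lo))
        if lo == hi
        else rng.integers(int(lo), int(hi) + 1, size=plan.n_sites).astype(float)
    )
    beta_gamma = np.asarray(beta_gamma, dtype=float)
    cov_cols = {
        name: rng.standard_normal(plan.n_sites) for name in gamma_covariates
    }
    x_gamma = np.column_stack(
        [np.ones(plan.n_sites)] + [cov_cols[n] for n in gamma_covariates]
    )
    if beta_gamma.size != x_gamma.shape[1]:
        raise ValueError("beta_gamma length mismatch with site design")
    eps = sigma * rng.standard_normal(plan.n_sites)
    gamma = np.exp(x_gamma @ beta_gamma + eps)
    y = rng.poisson(latent_n[cells] * gamma * effort)
    table = pd.DataFrame(
        {
            "site_id": [f"site_{i:04d}" for i in range(plan.n_sites)],
            "cell": cells,
            "effort_days": effort,
            "count": y,
            **cov_cols,
        }
    )
    return CameraSurvey(table=table, covariate_names=list(gamma_covariates))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[LandscapeGrid, np.ndarray, CameraSurvey, np.ndarray]:
    """Landscape, latent abundance, survey and the true spatial residual,
    all from one seed."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    grid = generate_landscape(config)
    omega = spatial_residual_field(config, seed=ss[1])
    latent = simulate_latent_abundance(
        grid, np.asarray(config.beta_lambda), omega, config.phi, seed=ss[2],
        config=config,
    )
    survey = simulate_camera_survey(
        grid,
        latent,
        config.camera_plan,
        np.asarray(config.beta_gamma),
        config.sigma,
        seed=ss[3],
        gamma_covariates=config.gamma_covariates,
    )
    return grid, latent, survey, omega


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait_table(n_species: int = 6, seed=None) -> pd.DataFrame:
    """Species trait table: body mass (kg) plus gut and diet type.

    ``n_species=6`` (default) returns the fixed ungulate roster with its
    literature body masses; other sizes draw synthetic species with
    lognormal masses and categorical traits from fixed vocabularies.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    if n_species == 6:
        return pd.DataFrame(
            {
                "species": DEFAULT_SPECIES,
                "body_mass_kg": [DEFAULT_BIOMASS_KG[s] for s in DEFAULT_SPECIES],
                "gut_type": [_DEFAULT_GUT[s] for s in DEFAULT_SPECIES],
                "diet_type": [_DEFAULT_DIET[s] for s in DEFAULT_SPECIES],
            }
        ).set_index("species")
    rng = np.random.default_rng(seed)
    names = [f"species_{i:02d}" for i in range(n_species)]
    return pd.DataFrame(
        {
            "species": names,
            "body_mass_kg": np.round(np.exp(rng.normal(4.5, 0.8, n_species)), 1),
            "gut_type": rng.choice(GUT_TYPES, n_species),
            "diet_type": rng.choice(DIET_TYPES, n_species),
        }
    ).set_index("species")


# ---------------------------------------------------------------------------
# planted community structure
# ---------------------------------------------------------------------------

def simulate_community_landscape(
    n_x: int = 40,
    n_y: int = 40,
    n_regimes: int = 5,
    species: list[str] | None = None,
    log_level_scale: float = 1.2,
    noise_sd: float = 0.15,
    seed=None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Multi-species density surfaces with k contiguous planted regimes.

    The grid is split into ``n_regimes`` contiguous regions (nearest planted
    seed cell); each region gets its own per-species log-density level
    (scaled by ``log_level_scale``), on top of which smooth lognormal noise
    of SD ``noise_sd`` is added.  Returns (surfaces by species, planted
    region label per cell, 1-based).
    """
    if n_regimes < 2:
        raise ValueError("need at least two regimes")
    species = list(species) if species is not None else list(DEFAULT_SPECIES)
    rng = np.random.default_rng(seed)
    rows, cols = np.divmod(np.arange(n_x * n_y), n_x)
    seeds = rng.choice(n_x * n_y, size=n_regimes, replace=False)
    sr, sc = np.divmod(seeds, n_x)
    d2 = (rows[:, None] - sr[None, :]) ** 2 + (cols[:, None] - sc[None, :]) ** 2
    labels = d2.argmin(axis=1) + 1
    levels = log_level_scale * rng.standard_normal((n_regimes, len(species)))
    surfaces: dict[str, np.ndarray] = {}
    for s_idx, name in enumerate(species):
        noise = _smooth_field((n_y, n_x), 2.0, rng).ravel() * noise_sd
        surfaces[name] = np.exp(levels[labels - 1, s_idx] + noise)
    return surfaces, labels


# ---------------------------------------------------------------------------
# vegetation plots
# ---------------------------------------------------------------------------

_SAPLING_SPECIES = ("carpinus", "acer", "picea", "tilia", "quercus")


def simulate_vegetation_plots(
    cluster_labels: np.ndarray,
    browse_prob_by_cluster: dict[int, float],
    n_plots: int = 500,
    seed=None,
    mean_saplings: float = 8.0,
    reserve_fraction: float = 0.5,
    species: tuple[str, ...] = _SAPLING_SPECIES,
) -> pd.DataFrame:
    """Regeneration plots with browsing outcomes that differ by herbiscape.

    Each plot is assigned the cluster of a random grid cell and a reserve
    flag; per-species sapling counts in the two height classes (<30 cm on
    the inner sub-plot, >=30 cm on the outer) are Poisson, and each >=30 cm
    sapling is browsed independently with its cluster's probability.

    Returns one row per plot x species with columns ``plot_id``, ``cluster``,
    ``reserve``, ``species``, ``count_lt30``, ``count_ge30``,
    ``browsed_ge30``.
    """
    if n_plots < 1:
        raise ValueError("need at least one plot")
    for c, p in browse_prob_by_cluster.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"browse probability for cluster {c} outside [0, 1]")
    labels = np.asarray(cluster_labels)
    missing = set(np.unique(labels)) - set(browse_prob_by_cluster)
    if missing:
        raise ValueError(f"no browse probability for clusters {sorted(missing)}")
    rng = np.random.default_rng(seed)
    plot_cells = rng.integers(0, labels.size, size=n_plots)
    plot_cluster = labels[plot_cells]
    reserve = rng.uniform(size=n_plots) < reserve_fraction
    rows = []
    per_species_mean = mean_saplings / len(species)
    for p in range(n_plots):
        prob = browse_prob_by_cluster[int(plot_cluster[p])]
        for s in species:
            lt30 = int(rng.poisson(per_species_mean))
            ge30 = int(rng.poisson(per_species_mean))
            browsed = int(rng.binomial(ge30, prob)) if ge30 > 0 else 0
            rows.append(
                {
                    "plot_id": f"plot_{p:04d}",
                    "cluster": int(plot_cluster[p]),
                    "reserve": int(reserve[p]),
                    "species": s,
                    "count_lt30": lt30,
                    "count_ge30": ge30,
                    "browsed_ge30": browsed,
                }
            )
    return pd.DataFrame(rows)
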