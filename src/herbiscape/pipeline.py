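"""Staged end-to-end pipeline:

simulate -> preprocess -> fit carnivores -> export risk covariates ->
fit herbivores -> predict -> community -> vegetation.

Every stage is a pure function of (inputs, config, seed); rerunning with
the same seed and config reproduces all CSV artifacts byte for byte.  The
carnivore models are fitted first and their posterior-mean density
surfaces, standardized like any other covariate, enter the herbivore
designs as predation-risk layers (density of a predator in a cell is
proportional to its encounter rate from the prey's perspective).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .abundance import CameraSurvey, SpatialAbundanceModel
from .community import HCPC, biomass_surfaces, fdis_map, pairwise_overlap
from .grid import LandscapeGrid
from .preprocess import screen_collinearity, standardize_covariates
from .predict import extract_spatial_effects, predict_lambda_surface
from .simulate import (
    DEFAULT_BIOMASS_KG,
    CameraPlan,
    CovariateSpec,
    SimulationConfig,
    simulate_camera_survey,
    simulate_latent_abundance,
    simulate_trait_table,
    simulate_vegetation_plots,
    generate_landscape,
    spatial_residual_field,
)
from .vegetation import browsing_intensity, fit_herbiscape_lm, recruitment_shift

__all__ = ["RunConfig", "SpeciesSpec", "run_pipeline", "PipelineError", "ALL_STAGES"]

ALL_STAGES = ("simulate", "preprocess", "fit", "predict", "community", "vegetation")


class PipelineError(RuntimeError):
    """A stage failed or its upstream artifacts are missing."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class SpeciesSpec:
    """True simulation parameters for one species.

    ``role`` is ``"carnivore"`` or ``"herbivore"``; carnivores are fitted
    first and feed risk covariates into the herbivore designs.
    """

    name: str
    role: str
    beta_lambda: list[float]
    beta_gamma: list[float] = field(default_factory=lambda: [-1.0])
    phi: float = 2.0
    sigma: float = 0.3


def _default_species() -> list[SpeciesSpec]:
    herb_betas = {
        "red_deer_female": [0.6, 0.7, -0.3],
        "red_deer_male": [0.3, 0.6, -0.2],
        "roe_deer": [0.9, -0.4, 0.5],
        "wild_boar": [0.7, 0.3, 0.4],
        "moose": [-0.4, -0.6, -0.3],
        "european_bison": [-0.2, 0.5, -0.6],
    }
    species = [SpeciesSpec("wolf", "carnivore", [-1.0, -0.5, 0.3], [-2.0], 1.5, 0.3)]
    species += [
        SpeciesSpec(name, "herbivore", beta) for name, beta in herb_betas.items()
    ]
    return species


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``profile`` switches sampler settings: ``"desk"`` (3 x 2,000
    iterations at the default demo scale) or ``"full"`` (3 chains x
    500,000 iterations, 400,000 burn-in, thinning 20).
    """

    seed: int = 0
    n_x: int = 15
    n_y: int = 15
    covariates: list[CovariateSpec] = field(
        default_factory=lambda: [
            CovariateSpec("openness", 2.5),
            CovariateSpec("canopy_height", 2.5),
        ]
    )
    species: list[SpeciesSpec] = field(default_factory=_default_species)
    n_sites: int = 60
    effort_range: tuple[float, float] = (20.0, 40.0)
    profile: str = "desk"
    n_iter: int = 2_000
    n_burn: int = 1_000
    thin: int = 5
    n_chains: int = 3
    basis_rank: int | None = 10
    n_max: int = 100
    n_clusters: int = 5
    consolidate: bool = True
    browse_prob_by_cluster: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.45, 3: 0.3, 4: 0.2, 5: 0.1}
    )
    n_plots: int = 400
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "full"):
            raise ValueError("profile must be 'desk' or 'full'")
        if self.profile == "full":
            self.n_iter, self.n_burn, self.thin = 500_000, 400_000, 20
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        roles = {s.role for s in self.species}
        if not roles <= {"carnivore", "herbivore"}:
            raise ValueError("species roles must be 'carnivore' or 'herbivore'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "covariates" in raw:
            raw["covariates"] = [CovariateSpec(**c) for c in raw["covariates"]]
        if "species" in raw:
            raw["species"] = [SpeciesSpec(**s) for s in raw["species"]]
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "effort_range" in raw:
            raw["effort_range"] = tuple(raw["effort_range"])
        if "browse_prob_by_cluster" in raw:
            raw["browse_prob_by_cluster"] = {
                int(k): float(v) for k, v in raw["browse_prob_by_cluster"].items()
            }
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages in dependency order; returns the run
    directory.  Disabled stages whose artifacts are needed downstream must
    have been produced by an earlier run into the same directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": []}
    (out / "config_snapshot.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True, default_flow_style=None)
    )
    ctx: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        _STAGE_FUNCS[stage](config, out, ctx, log)
        log["stages"].append(stage)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    ss = np.random.SeedSequence(config.seed)
    sim = SimulationConfig(
        n_x=config.n_x,
        n_y=config.n_y,
        covariates=config.covariates,
        beta_lambda=tuple([0.0] + [0.0] * len(config.covariates)),
        camera_plan=CameraPlan(config.n_sites, config.effort_range),
        seed=config.seed,
    )
    grid = generate_landscape(sim)
    hio.write_grid_rasters(out / "landscape.tif", grid)
    grid.covariate_table().to_csv(out / "covariates.csv", index_label="cell")
    children = ss.spawn(2 * len(config.species) + 1)
    for idx, sp in enumerate(config.species):
        spec = SimulationConfig(
            n_x=config.n_x,
            n_y=config.n_y,
            covariates=config.covariates,
            beta_lambda=tuple(sp.beta_lambda),
            beta_gamma=tuple(sp.beta_gamma),
            phi=sp.phi,
            sigma=sp.sigma,
            camera_plan=CameraPlan(config.n_sites, config.effort_range),
            seed=config.seed,
        )
        omega = spatial_residual_field(spec, seed=children[2 * idx])
        latent = simulate_latent_abundance(
            grid, np.asarray(sp.beta_lambda), omega, sp.phi,
            seed=children[2 * idx], config=spec,
        )
        survey = simulate_camera_survey(
            grid, latent, spec.camera_plan, np.asarray(sp.beta_gamma), sp.sigma,
            seed=children[2 * idx + 1],
        )
        survey.table.to_csv(out / f"survey_{sp.name}.csv", index=False)
    ctx["grid"] = grid
    log["n_cells"] = grid.n_cells


def _load_grid(config: RunConfig, out: Path, ctx: dict, stage: str) -> LandscapeGrid:
    if "grid" in ctx:
        return ctx["grid"]
    path = out / "covariates.csv"
    if not path.exists():
        raise PipelineError(stage, "missing landscape artifacts; run 'simulate' first")
    table = pd.read_csv(path, index_col="cell")
    grid = LandscapeGrid(
        n_x=config.n_x,
        n_y=config.n_y,
        covariates={c: table[c].to_numpy() for c in table.columns},
    )
    ctx["grid"] = grid
    return grid


def _load_survey(out: Path, name: str, stage: str) -> CameraSurvey:
    path = out / f"survey_{name}.csv"
    if not path.exists():
        raise PipelineError(stage, f"missing survey artifact for species {name!r}")
    table = pd.read_csv(path)
    extra = [
        c for c in table.columns if c not in ("site_id", "cell", "effort_days", "count")
    ]
    return CameraSurvey(table=table, covariate_names=extra)


def _stage_preprocess(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    grid = _load_grid(config, out, ctx, "preprocess")
    table, record = standardize_covariates(grid.covariate_table())
    record.to_csv(out / "standardization_record.csv", index_label="covariate")
    offending = screen_collinearity(table)
    pd.DataFrame(offending, columns=["a", "b", "r"]).to_csv(
        out / "collinearity_screen.csv", index=False
    )
    grid.covariates = {c: table[c].to_numpy() for c in table.columns}
    log["collinear_pairs"] = len(offending)


def _fit_species(
    config: RunConfig, grid: LandscapeGrid, survey: CameraSurvey, seed: int
) -> SpatialAbundanceModel:
    est = SpatialAbundanceModel(
        n_max=config.n_max,
        basis_rank=config.basis_rank,
        n_iter=config.n_iter,
        n_burn=config.n_burn,
        thin=config.thin,
        n_chains=config.n_chains,
        random_state=seed,
    )
    return est.fit(survey, grid)


def _stage_fit(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    grid = _load_grid(config, out, ctx, "fit")
    ss = np.random.SeedSequence(config.seed).spawn(len(config.species) + 8)
    fits: dict[str, SpatialAbundanceModel] = {}
    carnivores = [s for s in config.species if s.role == "carnivore"]
    herbivores = [s for s in config.species if s.role == "herbivore"]
    risk_layers: dict[str, np.ndarray] = {}
    for i, sp in enumerate(carnivores):
        survey = _load_survey(out, sp.name, "fit")
        fit = _fit_species(config, grid, survey, int(ss[i].generate_state(1)[0] % 2**31))
        fits[sp.name] = fit
        surface = predict_lambda_surface(
            fit.samples_, fit.design_.x_lambda, fit.design_.lambda_names, fit.basis_.k
        )
        risk = surface["mean"].to_numpy()
        risk_layers[f"risk_{sp.name}"] = (risk - risk.mean()) / risk.std()
    herb_grid = LandscapeGrid(
        n_x=grid.n_x,
        n_y=grid.n_y,
        cell_size=grid.cell_size,
        covariates={**grid.covariates, **risk_layers},
    )
    for i, sp in enumerate(herbivores):
        survey = _load_survey(out, sp.name, "fit")
        seed = int(ss[len(carnivores) + i].generate_state(1)[0] % 2**31)
        fits[sp.name] = _fit_species(config, herb_grid, survey, seed)
    for name, fit in fits.items():
        fit.summary_.to_csv(out / f"fit_{name}_summary.csv")
        fit.rhat_.to_csv(out / f"fit_{name}_rhat.csv", header=True)
    ctx["fits"] = fits
    ctx["herb_grid"] = herb_grid
    log["fitted_species"] = list(fits)
    log["acceptance"] = {n: f.acceptance_ for n, f in fits.items()}


def _require_fits(ctx: dict, stage: str) -> dict:
    if "fits" not in ctx:
        raise PipelineError(
            stage, "no fitted models in this run; enable the 'fit' stage"
        )
    return ctx["fits"]


def _stage_predict(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    fits = _require_fits(ctx, "predict")
    surfaces: dict[str, np.ndarray] = {}
    for name, fit in fits.items():
        surface = predict_lambda_surface(
            fit.samples_, fit.design_.x_lambda, fit.design_.lambda_names, fit.basis_.k
        )
        hio.write_surface_csv(out / f"lambda_{name}.csv", surface)
        grid = ctx.get("herb_grid") or ctx["grid"]
        hio.write_raster(
            out / f"lambda_{name}.tif",
            {"mean": surface["mean"].to_numpy()},
            (config.n_y, config.n_x),
            grid.cell_size,
        )
        sre = extract_spatial_effects(fit.samples_, fit.basis_.k)
        hio.write_surface_csv(out / f"sre_{name}.csv", sre)
        surfaces[name] = surface["mean"].to_numpy()
    ctx["surfaces"] = surfaces


def _stage_community(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    if "surfaces" not in ctx:
        raise PipelineError("community", "no predicted surfaces; enable 'predict'")
    herb_names = [s.name for s in config.species if s.role == "herbivore"]
    surfaces = {n: ctx["surfaces"][n] for n in herb_names}
    weights = {
        n: DEFAULT_BIOMASS_KG.get(n, 100.0) for n in herb_names
    }
    biomass = biomass_surfaces(surfaces, weights)
    overlap = pairwise_overlap(surfaces)
    overlap.to_csv(out / "pairwise_overlap.csv")
    traits = simulate_trait_table(6)
    traits = traits.loc[[n for n in traits.index if n in herb_names]]
    abundance = pd.DataFrame({n: surfaces[n] for n in traits.index})
    features = biomass.copy()
    if len(traits) >= 2:
        features["fdis"] = fdis_map(traits, abundance).to_numpy()
    est = HCPC(
        n_clusters=config.n_clusters,
        consolidate=config.consolidate,
        random_state=config.seed,
    ).fit(features)
    herb_map = features.copy()
    herb_map["cluster"] = est.labels_
    herb_map.to_csv(out / "herbiscape_map.csv", index_label="cell")
    est.profiles_.to_csv(out / "herbiscape_profiles.csv")
    est.inertia_gain_.to_csv(out / "inertia_gain.csv", header=True)
    hio.write_raster(
        out / "herbiscape_labels.tif",
        {"cluster": est.labels_.astype(float)},
        (config.n_y, config.n_x),
    )
    ctx["herbiscape_map"] = herb_map
    log["cluster_sizes"] = (
        pd.Series(est.labels_).value_counts().sort_index().to_dict()
    )


def _stage_vegetation(config: RunConfig, out: Path, ctx: dict, log: dict) -> None:
    if "herbiscape_map" in ctx:
        labels = ctx["herbiscape_map"]["cluster"].to_numpy()
    else:
        path = out / "herbiscape_map.csv"
        if not path.exists():
            raise PipelineError("vegetation", "missing herbiscape map; run 'community'")
        labels = pd.read_csv(path)["cluster"].to_numpy()
    probs = {
        c: config.browse_prob_by_cluster.get(int(c), 0.3) for c in np.unique(labels)
    }
    seed = int(np.random.SeedSequence(config.seed).spawn(100)[-1].generate_state(1)[0] % 2**31)
    plots = simulate_vegetation_plots(labels, probs, n_plots=config.n_plots, seed=seed)
    plots.to_csv(out / "vegetation_plots.csv", index=False)
    meta = plots.groupby("plot_id")[["cluster", "reserve"]].first()
    responses = {"browsing_intensity": browsing_intensity(plots)}
    for sp in ("carpinus", "acer"):
        responses[f"recruitment_shift_{sp}"] = recruitment_shift(plots, sp)
    for name, resp in responses.items():
        try:
            coefs, means = fit_herbiscape_lm(
                resp, meta["cluster"], meta["reserve"]
            )
        except ValueError as err:
            raise PipelineError("vegetation", str(err)) from err
        coefs.to_csv(out / f"vegetation_lm_{name}_coefs.csv")
        means.to_csv(out / f"vegetation_lm_{name}_means.csv", index=False)
    log["n_plots"] = config.n_plots


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "community": _stage_community,
    "vegetation": _stage_vegetation,
}
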