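import numpy as np
import pandas as pd
import pytest

from herbiscape.grid import build_adjacency, morans_i
from herbiscape.simulate import (
    CameraPlan,
    CovariateSpec,
    SimulationConfig,
    generate_landscape,
    simulate_camera_survey,
    simulate_community_landscape,
    simulate_latent_abundance,
    simulate_trait_table,
    simulate_vegetation_plots,
)


def _flat_grid(n_x, n_y, layers=("a",)):
    config = SimulationConfig(
        n_x=n_x,
        n_y=n_y,
        covariates=[CovariateSpec(n, 0.0) for n in layers],
        beta_lambda=tuple([0.0] * (1 + len(layers))),
        seed=3,
    )
    return generate_landscape(config), config


class TestGenerateLandscape:
    def test_layers_standardized(self):
        grid, _ = _flat_grid(12, 10)
        layer = grid.covariates["a"]
        assert layer.mean() == pytest.approx(0.0, abs=1e-12)
        assert layer.std() == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_bit_identical(self):
        g1, _ = _flat_grid(8, 8)
        g2, _ = _flat_grid(8, 8)
        assert np.array_equal(g1.covariates["a"], g2.covariates["a"])

    def test_smoothing_raises_morans_i(self):
        smooth_cfg = SimulationConfig(
            n_x=50, n_y=50,
            covariates=[CovariateSpec("s", 5.0), CovariateSpec("w", 0.0)],
            beta_lambda=(0.0, 0.0, 0.0), seed=5,
        )
        grid = generate_landscape(smooth_cfg)
        a, _ = build_adjacency((50, 50))
        assert morans_i(grid.covariates["s"], a) > morans_i(grid.covariates["w"], a)

    def test_duplicate_names_rejected(self):
        config = SimulationConfig(
            covariates=[CovariateSpec("x"), CovariateSpec("x")],
            beta_lambda=(0.0, 0.0, 0.0),
        )
        with pytest.raises(ValueError):
            generate_landscape(config)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_x=0, n_y=5)


class TestLatentAbundance:
    def test_null_coefficients_give_unit_lambda(self):
        grid, _ = _flat_grid(5, 5)
        # beta = 0, omega = 0 means lambda = 1; with huge phi, N ~ Poisson(1)
        n = simulate_latent_abundance(grid, [0.0, 0.0], np.zeros(25), 1e9, seed=0)
        assert n.shape == (25,)
        assert n.min() >= 0

    def test_poisson_limit_moments(self):
        grid, _ = _flat_grid(500, 200)  # 1e5 cells
        lam = 3.0
        n = simulate_latent_abundance(
            grid, [np.log(lam), 0.0], np.zeros(grid.n_cells), 1e8, seed=11
        )
        assert n.mean() == pytest.approx(lam, abs=0.05)
        assert n.var() == pytest.approx(lam, rel=0.05)

    def test_negbin_variance_identity(self):
        grid, _ = _flat_grid(500, 200)
        lam, phi = 3.0, 2.0
        n = simulate_latent_abundance(
            grid, [np.log(lam), 0.0], np.zeros(grid.n_cells), phi, seed=12
        )
        assert n.mean() == pytest.approx(lam, rel=0.02)
        assert n.var() == pytest.approx(lam + lam**2 / phi, rel=0.05)

    def test_invalid_phi_rejected(self):
        grid, _ = _flat_grid(5, 5)
        with pytest.raises(ValueError):
            simulate_latent_abundance(grid, [0.0, 0.0], np.zeros(25), 0.0)

    def test_beta_length_mismatch_rejected(self):
        grid, _ = _flat_grid(5, 5)
        with pytest.raises(ValueError):
            simulate_latent_abundance(grid, [0.0], np.zeros(25), 1.0)


class TestCameraSurvey:
    def test_zero_abundance_gives_zero_counts(self):
        grid, _ = _flat_grid(5, 5)
        survey = simulate_camera_survey(
            grid, np.zeros(25, dtype=int), CameraPlan(30, (5, 10)), [-0.5], 0.4, seed=2
        )
        assert (survey.table["count"] == 0).all()

    def test_poisson_mean_with_known_rate(self):
        # N = 2 everywhere, gamma = 1, d = 1.5 -> E[y] = 3
        grid, _ = _flat_grid(200, 200)
        plan = CameraPlan(n_sites=40_000, effort_range=(1.5, 1.5), max_per_cell=1)
        survey = simulate_camera_survey(
            grid, np.full(grid.n_cells, 2), plan, [0.0], 0.0, seed=4
        )
        assert survey.table["count"].mean() == pytest.approx(3.0, abs=0.05)

    def test_effort_offset_is_linear(self):
        grid, _ = _flat_grid(60, 60)
        n = np.full(grid.n_cells, 2)
        mean_short = simulate_camera_survey(
            grid, n, CameraPlan(3000, (10, 10), 1), [0.0], 0.0, seed=6
        ).table["count"].mean()
        mean_long = simulate_camera_survey(
            grid, n, CameraPlan(3000, (20, 20), 1), [0.0], 0.0, seed=6
        ).table["count"].mean()
        assert mean_long / mean_short == pytest.approx(2.0, rel=0.05)

    def test_aggregated_counts_poisson_at_sigma_zero(self):
        # sites sharing a cell with sigma=0: total count is Poisson with
        # rate N_j * sum gamma_i d_i -> dispersion index about 1
        grid, _ = _flat_grid(40, 40)
        n = np.full(grid.n_cells, 3)
        plan = CameraPlan(n_sites=3200, effort_range=(10, 10), max_per_cell=2)
        survey = simulate_camera_survey(grid, n, plan, [np.log(0.05)], 0.0, seed=8)
        totals = survey.table.groupby("cell")["count"].sum()
        full = totals[survey.table.groupby("cell").size() == 2]
        dispersion = full.var() / full.mean()
        assert dispersion == pytest.approx(1.0, abs=0.15)

    def test_effort_below_one_day_rejected(self):
        with pytest.raises(ValueError):
            CameraPlan(10, (0.5, 2.0))


class TestTraitTable:
    def test_default_roster_masses(self):
        traits = simulate_trait_table(6)
        assert traits.loc["red_deer_female", "body_mass_kg"] == 90.0
        assert traits.loc["european_bison", "body_mass_kg"] == 400.0
        assert list(traits.columns) == ["body_mass_kg", "gut_type", "diet_type"]
        assert traits.index.is_unique

    def test_single_species_table(self):
        traits = simulate_trait_table(1, seed=0)
        assert len(traits) == 1

    def test_seeded_determinism_and_vocabularies(self):
        t1 = simulate_trait_table(10, seed=42)
        t2 = simulate_trait_table(10, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["gut_type"]) <= {"ruminant", "monogastric"}

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_trait_table(0)


class TestCommunityLandscape:
    def test_planted_labels_are_contiguous_range(self):
        surfaces, labels = simulate_community_landscape(
            n_x=20, n_y=20, n_regimes=4, seed=1
        )
        assert set(np.unique(labels)) == {1, 2, 3, 4}
        assert all(v.size == 400 for v in surfaces.values())
        assert all((v > 0).all() for v in surfaces.values())

    def test_deterministic(self):
        s1, l1 = simulate_community_landscape(n_x=10, n_y=10, seed=9)
        s2, l2 = simulate_community_landscape(n_x=10, n_y=10, seed=9)
        assert np.array_equal(l1, l2)
        for k in s1:
            assert np.array_equal(s1[k], s2[k])


class TestVegetationPlots:
    def test_zero_probability_means_no_browsing(self):
        labels = np.array([1, 1, 2, 2])
        plots = simulate_vegetation_plots(labels, {1: 0.0, 2: 0.0}, 50, seed=0)
        assert (plots["browsed_ge30"] == 0).all()

    def test_probability_one_browses_everything(self):
        labels = np.array([1, 2])
        plots = simulate_vegetation_plots(labels, {1: 1.0, 2: 1.0}, 50, seed=0)
        assert (plots["browsed_ge30"] == plots["count_ge30"]).all()

    def test_cluster_means_recover_probabilities(self):
        labels = np.array([1] * 10 + [2] * 10)
        plots = simulate_vegetation_plots(labels, {1: 0.6, 2: 0.2}, 1000, seed=3)
        per_plot = plots.groupby(["plot_id", "cluster"])[
            ["count_ge30", "browsed_ge30"]
        ].sum().reset_index()
        per_plot = per_plot[per_plot["count_ge30"] > 0]
        per_plot["intensity"] = per_plot["browsed_ge30"] / per_plot["count_ge30"]
        means = per_plot.groupby("cluster")["intensity"].mean()
        assert means[1] == pytest.approx(0.6, abs=0.05)
        assert means[2] == pytest.approx(0.2, abs=0.05)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_vegetation_plots(np.array([1]), {1: 1.5}, 10)

    def test_missing_cluster_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_vegetation_plots(np.array([1, 2]), {1: 0.5}, 10)
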