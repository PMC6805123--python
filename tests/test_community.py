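import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from herbiscape.community import (
    HCPC,
    biomass_surfaces,
    compute_fdis,
    fdis_map,
    gower_distance,
    hcpc_cluster,
    pairwise_overlap,
)
from herbiscape.simulate import DEFAULT_BIOMASS_KG, simulate_trait_table


def _two_species(mass=(10.0, 30.0), gut=("ruminant", "monogastric")):
    return pd.DataFrame(
        {"body_mass_kg": mass, "gut_type": gut},
        index=pd.Index(["sp1", "sp2"], name="species"),
    )


class TestGower:
    def test_hand_computed_mixed_distance(self):
        traits = _two_species()
        d = gower_distance(traits)
        # mass range-normalized: |10-30|/20 = 1; categorical mismatch: 1
        assert d[0, 1] == pytest.approx(1.0)
        traits2 = _two_species(gut=("ruminant", "ruminant"))
        assert gower_distance(traits2)[0, 1] == pytest.approx(0.5)

    def test_zero_diagonal_symmetry(self):
        traits = simulate_trait_table(6)
        d = gower_distance(traits)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert d.max() <= 1.0 + 1e-12

    def test_missing_values_rejected(self):
        traits = _two_species()
        traits.loc["sp1", "body_mass_kg"] = np.nan
        with pytest.raises(ValueError):
            gower_distance(traits)


class TestFDis:
    def test_single_species_is_zero(self):
        traits = _two_species().iloc[:1]
        assert compute_fdis(traits, [3.0]) == 0.0

    def test_two_species_equal_weights_half_distance(self):
        traits = _two_species(gut=("ruminant", "ruminant"))
        d = gower_distance(traits)[0, 1]
        assert compute_fdis(traits, [1.0, 1.0]) == pytest.approx(d / 2, abs=1e-12)

    def test_two_species_weighted_closed_form(self):
        traits = _two_species()
        d = gower_distance(traits)[0, 1]
        # centroid at 0.75/0.25 split: FDis = 2 * d * 0.75 * 0.25
        assert compute_fdis(traits, [0.75, 0.25]) == pytest.approx(
            0.375 * d, abs=1e-12
        )

    @given(scale=hst.floats(1e-3, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_rescaling_abundances_invariant(self, scale):
        traits = simulate_trait_table(6)
        a = np.array([1.0, 2.0, 0.5, 3.0, 0.1, 1.5])
        base = compute_fdis(traits, a)
        assert compute_fdis(traits, a * scale) == pytest.approx(base, abs=1e-12)

    def test_equal_abundances_match_unweighted_geometry(self):
        traits = simulate_trait_table(6)
        from herbiscape.community import trait_space

        coords = trait_space(traits)
        centroid = coords.mean(axis=0)
        expected = np.sqrt(((coords - centroid) ** 2).sum(axis=1)).mean()
        assert compute_fdis(traits, np.ones(6)) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            compute_fdis(_two_species(), [0.0, 0.0])

    def test_fdis_map_matches_per_cell_calls(self, rng):
        traits = simulate_trait_table(6)
        abundances = pd.DataFrame(
            rng.uniform(0.1, 5.0, size=(10, 6)), columns=traits.index
        )
        mapped = fdis_map(traits, abundances)
        for i in range(10):
            assert mapped.iloc[i] == pytest.approx(
                compute_fdis(traits, abundances.iloc[i].to_numpy()), abs=1e-10
            )


class TestBiomass:
    def test_unit_densities_of_full_roster_total(self):
        surfaces = {s: np.ones(4) for s in DEFAULT_BIOMASS_KG}
        table = biomass_surfaces(surfaces, DEFAULT_BIOMASS_KG)
        assert np.allclose(table["total_biomass"], 940.0)

    def test_zero_densities_zero_biomass(self):
        surfaces = {s: np.zeros(5) for s in DEFAULT_BIOMASS_KG}
        table = biomass_surfaces(surfaces, DEFAULT_BIOMASS_KG)
        assert (table.to_numpy() == 0).all()

    def test_linearity_in_one_species(self, rng):
        surfaces = {s: rng.uniform(0, 2, 6) for s in DEFAULT_BIOMASS_KG}
        base = biomass_surfaces(surfaces, DEFAULT_BIOMASS_KG)
        surfaces2 = dict(surfaces)
        surfaces2["moose"] = 2 * surfaces["moose"]
        doubled = biomass_surfaces(surfaces2, DEFAULT_BIOMASS_KG)
        extra = doubled["biomass_moose"] - base["biomass_moose"]
        assert np.allclose(doubled["biomass_moose"], 2 * base["biomass_moose"])
        assert np.allclose(
            doubled["total_biomass"], base["total_biomass"] + extra
        )

    def test_total_conservation_exact(self, rng):
        surfaces = {s: rng.uniform(0, 3, 20) for s in DEFAULT_BIOMASS_KG}
        table = biomass_surfaces(surfaces, DEFAULT_BIOMASS_KG)
        species_cols = [c for c in table.columns if c != "total_biomass"]
        assert np.allclose(
            table["total_biomass"], table[species_cols].sum(axis=1), atol=1e-9
        )

    def test_missing_weight_rejected(self):
        with pytest.raises(KeyError):
            biomass_surfaces({"x": np.ones(3)}, {})


class TestPairwiseOverlap:
    def test_self_correlation_unity_and_negation(self, rng):
        x = rng.standard_normal(500)
        corr = pairwise_overlap({"a": x, "b": x, "c": -(x - x.mean()) + x.mean()})
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_independent_surfaces_near_zero(self, rng):
        corr = pairwise_overlap(
            {"a": rng.standard_normal(2_500), "b": rng.standard_normal(2_500)}
        )
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_constant_surface_flagged_nan(self, rng):
        corr = pairwise_overlap({"a": np.ones(100), "b": rng.standard_normal(100)})
        assert np.isnan(corr.loc["a", "b"])
        assert np.isnan(corr.loc["a", "a"])


def _ward_heights_bruteforce(points):
    """Lance-Williams agglomeration oracle for Ward linkage."""
    clusters = {i: 1 for i in range(len(points))}
    dist = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            dist[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: kv[1])
        heights.append(dij)
        ni, nj = clusters[i], clusters[j]
        new = {}
        for (a, b), dab in dist.items():
            if {a, b} & {i, j}:
                continue
            new[(a, b)] = dab
        for m, nm in clusters.items():
            if m in (i, j):
                continue
            dim = dist[tuple(sorted((i, m)))]
            djm = dist[tuple(sorted((j, m)))]
            d2 = (
                (ni + nm) * dim**2 + (nj + nm) * djm**2 - nm * dij**2
            ) / (ni + nj + nm)
            new[tuple(sorted((m, next_id)))] = float(np.sqrt(d2))
        del clusters[i], clusters[j]
        clusters[next_id] = ni + nj
        dist = new
        next_id += 1
    return heights


class TestHCPC:
    def test_two_blobs_perfectly_recovered(self, rng):
        blob1 = rng.normal(0.0, 0.3, size=(30, 3))
        blob2 = rng.normal(6.0, 0.3, size=(30, 3))
        features = pd.DataFrame(np.vstack([blob1, blob2]))
        labels, _ = hcpc_cluster(features, k=2, seed=0)
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_ward_merge_heights_match_lance_williams_oracle(self, rng):
        points = rng.standard_normal((6, 2))
        est = HCPC(n_clusters=2, standardize=False, consolidate=False).fit(
            pd.DataFrame(points)
        )
        ours = est.linkage_[:, 2]
        expected = _ward_heights_bruteforce(est.scores_)
        assert np.allclose(ours, expected, atol=1e-9)

    def test_row_permutation_same_partition(self, rng):
        features = pd.DataFrame(rng.standard_normal((40, 4)))
        perm = rng.permutation(40)
        l1, _ = hcpc_cluster(features, k=3, seed=0)
        l2, _ = hcpc_cluster(features.iloc[perm].reset_index(drop=True), k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_labels_contiguous_one_based(self, rng):
        features = pd.DataFrame(rng.standard_normal((25, 3)))
        labels, gains = hcpc_cluster(features, k=4, seed=1)
        assert set(labels) == {1, 2, 3, 4}
        assert (gains.index >= 2).all()

    def test_k_exceeding_distinct_rows_rejected(self):
        features = pd.DataFrame([[1.0, 2.0]] * 5)
        with pytest.raises(ValueError):
            hcpc_cluster(features, k=3)

    def test_inertia_gains_decrease_for_separated_blobs(self, rng):
        blobs = np.vstack(
            [rng.normal(c, 0.2, size=(20, 2)) for c in (0.0, 5.0, 10.0)]
        )
        est = HCPC(n_clusters=3, consolidate=False).fit(pd.DataFrame(blobs))
        gains = est.inertia_gain_
        # the first cuts (k=2, 3) release far more inertia than later ones
        assert gains[2] > gains[4]
        assert gains[3] > gains[4]
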