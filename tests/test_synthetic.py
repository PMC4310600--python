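import dataclasses

import numpy as np
import pytest
from scipy import stats

import rangeshift as rs
from rangeshift.synthetic import (
    _stratum_counts,
    occupancy_probabilities,
    perturb_scenario,
    simulate_plots,
)
from rangeshift.validation import replicate_shifts


class TestLandscape:
    def test_temperature_field_is_exactly_linear(self):
        L = rs.LandscapeConfig()
        plots = simulate_plots(L, 500, np.random.default_rng(0))
        expected = (
            L.t0
            - L.lat_gradient * (plots["latitude"] - L.lat_min)
            - L.lapse_rate * plots["elevation_m"] / 1000.0
        )
        np.testing.assert_array_equal(plots["mat_c"].to_numpy(), expected.to_numpy())

    def test_stratum_counts_follow_design_density(self):
        L = rs.LandscapeConfig()
        counts = _stratum_counts(L, 12000)
        fr = np.array([f / d for _, f, d in L.strata])
        expected = fr / fr.sum() * 12000
        assert sum(counts) == 12000
        np.testing.assert_allclose(counts, expected, atol=1.0)

    def test_weights_equal_configured_density(self):
        plots = simulate_plots(rs.LandscapeConfig(), 200, np.random.default_rng(1))
        by = plots.groupby("stratum")["weight"].unique()
        assert list(by["CA-OR"]) == [24.0] and list(by["WA"]) == [26.6]

    def test_latitudes_quasi_uniform_within_stratum(self):
        L = rs.LandscapeConfig()
        plots = simulate_plots(L, 5000, np.random.default_rng(2))
        south = plots.loc[plots["stratum"] == "CA-OR", "latitude"]
        lo, hi = L.lat_min, L.lat_min + 0.7 * (L.lat_max - L.lat_min)
        # stratified-grid jitter: no more than one plot per slice, so the
        # empirical CDF hugs the uniform CDF far tighter than an iid draw
        grid = np.linspace(lo, hi, 21)
        ecdf = np.searchsorted(np.sort(south), grid) / len(south)
        np.testing.assert_allclose(ecdf, (grid - lo) / (hi - lo), atol=0.01)

    def test_too_few_plots_rejected(self):
        with pytest.raises(rs.ConfigurationError):
            simulate_plots(rs.LandscapeConfig(), 5, np.random.default_rng(0))


class TestGeneratorDeterminism:
    def test_same_seed_gives_byte_identical_csvs(self, tmp_path):
        niches = rs.default_niches(n_species=4, delta=0.1)
        a = rs.generate_inventory(rs.LandscapeConfig(), niches, 500, 7, tmp_path / "a")
        b = rs.generate_inventory(rs.LandscapeConfig(), niches, 500, 7, tmp_path / "b")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        niches = rs.default_niches(n_species=4)
        a = rs.generate_inventory(rs.LandscapeConfig(), niches, 500, 7, tmp_path / "a")
        b = rs.generate_inventory(rs.LandscapeConfig(), niches, 500, 8, tmp_path / "c")
        assert a[0].read_bytes() != b[0].read_bytes()

    def test_empty_species_list_is_config_error(self):
        with pytest.raises(rs.ConfigurationError):
            rs.simulate_inventory(rs.LandscapeConfig(), [], 100, 0)


class TestTruth:
    def test_zero_delta_means_identical_population_means(self):
        niches = rs.default_niches(n_species=6, delta=0.0)
        plots = simulate_plots(rs.LandscapeConfig(), 2000, np.random.default_rng(3))
        truth = rs.population_truth(plots, niches)
        np.testing.assert_array_equal(
            truth["population_seedling_mean_mat"], truth["population_tree_mean_mat"]
        )

    def test_positive_delta_moves_seedling_population_colder(self):
        niches = rs.default_niches(n_species=6, delta=0.2)
        plots = simulate_plots(rs.LandscapeConfig(), 2000, np.random.default_rng(3))
        truth = rs.population_truth(plots, niches)
        assert (
            truth["population_seedling_mean_mat"] < truth["population_tree_mean_mat"]
        ).all()


class TestTallies:
    def test_tally_passes_io_validation_and_counts_positive(self, small_inventory):
        plots, tally, _, _ = small_inventory
        validated = rs.io_model.validate_tally(tally, plots)
        assert (validated["count"] >= 1).all()
        measured = validated["diameter_cm"].dropna()
        assert (measured >= 2.54).all()

    def test_small_stems_underrepresented_by_footprint_ratio(self, small_inventory):
        # detection thins stems < 12.7 cm by 54/672.5; with the default
        # lognormal mix the detected small:large ratio must drop accordingly
        _, tally, _, _ = small_inventory
        measured = tally["diameter_cm"].dropna()
        frac_small = (measured < 12.7).mean()
        assert frac_small < 0.25  # would be > 0.5 without thinning


class TestScenarios:
    def test_empty_scenario_list_is_identity(self):
        niches = rs.default_niches(n_species=3)
        assert perturb_scenario(niches, []) == niches

    def test_unknown_scenario_rejected(self):
        with pytest.raises(rs.ConfigurationError):
            perturb_scenario(rs.default_niches(n_species=2), "volcano")

    def test_pathogen_patch_with_zero_strength_changes_nothing(self):
        niches = rs.default_niches(n_species=2)
        plots = simulate_plots(rs.LandscapeConfig(), 500, np.random.default_rng(4))
        patched = perturb_scenario(niches, "pathogen_patch", patch_strength=0.0)
        for base, pert in zip(niches, patched):
            ps0, pt0 = occupancy_probabilities(plots, base)
            ps1, pt1 = occupancy_probabilities(plots, pert)
            np.testing.assert_array_equal(ps0, ps1)
            np.testing.assert_array_equal(pt0, pt1)

    def test_edge_contraction_suppresses_only_warm_side_seedlings(self):
        (niche,) = perturb_scenario(
            [rs.SpeciesNiche("X", mu_tree=9.0, sigma=2.0, delta=0.1)], "edge_contraction"
        )
        plots = simulate_plots(rs.LandscapeConfig(), 500, np.random.default_rng(4))
        ps0, pt0 = occupancy_probabilities(plots, dataclasses.replace(niche, warm_edge_factor=1.0))
        ps1, pt1 = occupancy_probabilities(plots, niche)
        warm = plots["mat_c"].to_numpy() > 11.0
        np.testing.assert_array_equal(pt0, pt1)  # trees untouched
        np.testing.assert_array_equal(ps0[~warm], ps1[~warm])
        assert (ps1[warm] < ps0[warm]).all()

    def test_elevational_confound_remaps_axis_through_lapse_rate(self):
        L = rs.LandscapeConfig()
        base = rs.default_niches(n_species=5, delta=0.12, sigma=2.0)
        conf = perturb_scenario(base, "elevational_confound", L)
        for n in conf:
            assert n.axis == "elevation"
            np.testing.assert_allclose(n.sigma, 2.0 * 1000 / L.lapse_rate)
            np.testing.assert_allclose(n.delta, 0.12 * 1000 / L.lapse_rate)
        # colder original centre -> higher elevation centre
        mus = [n.mu_tree for n in conf]
        assert mus == sorted(mus, reverse=True)


class TestRecoveredShiftMonotonicity:
    def test_recovered_shift_increases_with_planted_delta(self):
        """The recovered temperature shift magnitude grows monotonically in
        the planted δ (Spearman trend over δ ∈ {0, 0.06, 0.12, 0.24})."""
        deltas = [0.0, 0.06, 0.12, 0.24]
        means = []
        for k, delta in enumerate(deltas):
            niches = rs.default_niches(n_species=8, delta=delta)
            reps = []
            for s in np.random.SeedSequence(100 + k).spawn(100):
                rep = replicate_shifts(
                    rs.LandscapeConfig(), niches, 2000, np.random.default_rng(s)
                )
                reps.append(-rep.combined["mat_c"]["mean_diff"])
            means.append(np.mean(reps))
        rho, _ = stats.spearmanr(deltas, means)
        assert rho > 0
        assert means[0] < means[-1]
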