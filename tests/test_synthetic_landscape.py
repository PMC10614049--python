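"""Generator contracts: determinism, drift, biased placement, injection."""
import numpy as np
import pytest
from scipy import stats

from cfimpact import ScenarioConfig, inject_effect, mann_kendall
from cfimpact.covariates import feature_distance_raster
from cfimpact.errors import ConfigurationError, GenerationError
from cfimpact.synthetic_landscape import (
    generate_surfaces,
    place_zones,
    placement_probabilities,
    simulate_panel,
)
from shapely.geometry import LineString

from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"grid_rows": 16},
            {"years": (2000, 2016)},            # span < 18 years
            {"cell_size": 0.0},
            {"noise_sd": -1.0},
            {"establishment_years": (1980,)},   # outside span
            {"deforestation_base_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ConfigurationError):
            small_config(**overrides)

    def test_cohort_effects_follow_linear_formula(self):
        cfg = small_config(effect_level=2.0, effect_trend=0.5,
                           cohort_effect_slope=-0.05)
        oldest = min(cfg.establishment_years)
        for est in cfg.establishment_years:
            level, trend = cfg.cohort_effects(est)
            assert level == pytest.approx(2.0 - 0.05 * (est - oldest))
            assert trend == pytest.approx(0.5 - 0.05 * (est - oldest))

    def test_later_cohorts_get_strictly_smaller_effects(self):
        cfg = small_config(cohort_effect_slope=-0.05)
        levels = [cfg.cohort_effects(e)[0] for e in sorted(cfg.establishment_years)]
        assert all(a > b for a, b in zip(levels, levels[1:]))


class TestSurfaces:
    def test_deterministic_given_seed(self):
        cfg = small_config(seed=42)
        a, b = generate_surfaces(cfg), generate_surfaces(cfg)
        for name in ("elevation", "slope", "dist_road", "dist_village"):
            assert np.array_equal(a.raster(name), b.raster(name))

    def test_different_seed_changes_fields(self):
        a = generate_surfaces(small_config(seed=1))
        b = generate_surfaces(small_config(seed=2))
        assert not np.array_equal(a.elevation, b.elevation)

    def test_single_road_distance_grows_by_cell_per_column(self):
        # vertical road through column 2 of a 5x5 grid, 30-m cells
        road = LineString([(2.5 * 30, 0.0), (2.5 * 30, 5 * 30.0)])
        dist = feature_distance_raster([road], (5, 5), 30.0)
        for col in range(5):
            assert dist[:, col] == pytest.approx(abs(col - 2) * 30.0)

    def test_slope_derived_from_elevation(self):
        surf = generate_surfaces(small_config())
        assert surf.slope.min() >= 0
        assert surf.slope.max() < 90


class TestPanelSimulation:
    def test_no_dynamics_means_constant_tcc(self):
        cfg = small_config(baseline_tcc_trend=0.0, noise_sd=0.0,
                           deforestation_base_rate=0.0)
        panel = simulate_panel(cfg, generate_surfaces(cfg))
        assert np.array_equal(panel.tcc[0], panel.tcc[-1])

    def test_closed_form_drift_without_noise(self):
        # -0.5 %/yr over a 20-year interval: mean falls by exactly 10 points
        cfg = small_config(
            years=(1995, 2015), baseline_tcc_trend=-0.5, noise_sd=0.0,
            deforestation_base_rate=0.0, water_fraction=0.0,
            tcc_init_mean=55.0, tcc_init_sd=8.0, tcc_init_range=(30.0, 80.0),
            tcc_elevation_loading=0.0, establishment_years=(1997, 2003),
        )
        panel = simulate_panel(cfg, generate_surfaces(cfg))
        drop = panel.tcc[0].mean() - panel.tcc[-1].mean()
        assert drop == pytest.approx(0.5 * 20, abs=1e-9)

    def test_landscape_mean_trend_detected_by_mann_kendall(self):
        cfg = small_config(seed=5)
        panel = simulate_panel(cfg, generate_surfaces(cfg))
        series = panel.tcc.mean(axis=(1, 2))
        assert panel.n_years == 31
        assert mann_kendall(series).s < 0

    def test_tcc_bounds_and_binary_forest(self, demo_scene):
        panel = demo_scene["panel"]
        assert panel.tcc.min() >= 0 and panel.tcc.max() <= 100
        assert set(np.unique(panel.forest)) <= {0, 1}

    def test_clearing_reduces_forest_over_time(self):
        cfg = small_config(deforestation_base_rate=0.05, seed=9)
        panel = simulate_panel(cfg, generate_surfaces(cfg))
        assert panel.forest[-1].sum() < panel.forest[0].sum()

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=13)
        a = simulate_panel(cfg, generate_surfaces(cfg))
        b = simulate_panel(cfg, generate_surfaces(cfg))
        assert np.array_equal(a.tcc, b.tcc)
        assert np.array_equal(a.landcover, b.landcover)


class TestZonePlacement:
    def test_unbiased_coefficients_give_uniform_probabilities(self):
        cfg = small_config(placement_bias_coefs={})
        surf = generate_surfaces(cfg)
        eligible = np.ones((cfg.grid_rows, cfg.grid_cols), dtype=bool)
        probs = placement_probabilities(cfg, surf, eligible)
        assert np.allclose(probs, 1.0 / eligible.size)

    def test_uniform_seed_draws_pass_chi_square_gof(self, rng):
        # 500 seed draws under the null of uniform placement, binned by quadrant
        cfg = small_config(placement_bias_coefs={})
        surf = generate_surfaces(cfg)
        eligible = np.ones((cfg.grid_rows, cfg.grid_cols), dtype=bool)
        probs = placement_probabilities(cfg, surf, eligible).ravel()
        draws = rng.choice(probs.size, size=500, p=probs)
        r, c = np.unravel_index(draws, eligible.shape)
        quadrant = (r >= 16).astype(int) * 2 + (c >= 16).astype(int)
        counts = np.bincount(quadrant, minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_positive_elevation_bias_raises_zone_elevation(self):
        cfg = small_config(grid_rows=64, grid_cols=64, n_zones=5,
                           zone_target_area=40,
                           placement_bias_coefs={"elevation": 3.0}, seed=21)
        surf = generate_surfaces(cfg)
        panel = simulate_panel(cfg, surf)
        zones, _ = place_zones(cfg, surf, panel)
        inside = zones.labels >= 0
        assert surf.elevation[inside].mean() > surf.elevation[~inside].mean()

    def test_no_zones_gives_empty_zoneset_and_valid_panel(self):
        cfg = small_config(n_zones=0)
        surf = generate_surfaces(cfg)
        panel = simulate_panel(cfg, surf)
        zones, truth = place_zones(cfg, surf, panel)
        assert zones.table.empty and truth.table.empty
        assert (zones.labels == -1).all()

    def test_zones_disjoint_from_exclusions(self, demo_scene):
        zones = demo_scene["zones"]
        assert not (zones.exclusion_mask() & (zones.labels >= 0)).any()

    def test_ground_truth_zones_exist_in_zoneset(self, demo_scene):
        zone_ids = set(demo_scene["zones"].table["zone_id"])
        assert set(demo_scene["truth"].table["zone_id"]) <= zone_ids

    def test_impossible_packing_raises_generation_error(self):
        cfg = small_config(n_zones=40, zone_target_area=200)
        surf = generate_surfaces(cfg)
        panel = simulate_panel(cfg, surf)
        with pytest.raises(GenerationError):
            place_zones(cfg, surf, panel)


class TestEffectInjection:
    def test_null_effect_leaves_panel_identical(self):
        cfg = small_config(effect_level=0.0, effect_trend=0.0)
        surf = generate_surfaces(cfg)
        panel = simulate_panel(cfg, surf)
        zones, truth = place_zones(cfg, surf, panel)
        out = inject_effect(panel, zones, truth)
        assert np.array_equal(out.tcc, panel.tcc)
        assert np.array_equal(out.landcover, panel.landcover)

    def test_injected_gain_matches_hand_formula(self, base_scene):
        # level 2 + trend 0.5 => +4.0 at four years after establishment
        cfg = base_scene["config"]
        assert (cfg.effect_level, cfg.effect_trend) == (2.0, 0.5)
        panel, zones, truth = (base_scene["panel"], base_scene["zones"],
                               base_scene["truth"])
        out = inject_effect(panel, zones, truth)
        zone = truth.table.iloc[0]
        est = int(zone["est_year"])
        yi = panel.year_index(est + 4)
        mask = (zones.labels == zone["zone_id"]) & (panel._sim.cleared_year < 0)
        gain = out.tcc[yi][mask] - panel.tcc[yi][mask]
        interior = (panel.tcc[yi][mask] > 5) & (panel.tcc[yi][mask] < 90)
        assert gain[interior] == pytest.approx(2.0 + 0.5 * 4, abs=1e-9)

    def test_establishment_year_itself_unmodified(self, base_scene):
        panel, zones, truth = (base_scene["panel"], base_scene["zones"],
                               base_scene["truth"])
        out = inject_effect(panel, zones, truth)
        zone = truth.table.iloc[0]
        yi = panel.year_index(int(zone["est_year"]))
        mask = zones.labels == zone["zone_id"]
        assert np.array_equal(out.tcc[yi][mask], panel.tcc[yi][mask])

    def test_protection_reverts_post_establishment_clearings(self):
        cfg = small_config(grid_rows=64, grid_cols=64, n_zones=4,
                           zone_target_area=60,
                           deforestation_base_rate=0.08, seed=17)
        surf = generate_surfaces(cfg)
        panel = simulate_panel(cfg, surf)
        zones, truth = place_zones(cfg, surf, panel)
        unprotected = inject_effect(panel, zones, truth, protection_factor=0.0)
        protected = inject_effect(panel, zones, truth, protection_factor=1.0)
        inside = zones.labels >= 0
        assert (protected.forest[-1][inside].sum()
                >= unprotected.forest[-1][inside].sum())
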