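"""Properties of the synthetic study-system generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faunarange.periods import TimePeriod
from faunarange.phylo import tree_covariance
from faunarange.rasters import read_ascii_grid
from faunarange.spatial import PREDICTORS
from faunarange.synthetic import (
    SimulationConfig,
    sample_locality_records,
    simulate_cell_loss_table,
    simulate_landscape,
    simulate_species_histories,
    simulate_tree,
)


class TestLandscape:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=5, raster_cellsize_deg=0.5)
        r1 = simulate_landscape(cfg).rasters
        r2 = simulate_landscape(cfg).rasters
        for p in PREDICTORS:
            np.testing.assert_array_equal(r1[p].values, r2[p].values)

    def test_different_seeds_differ(self):
        a = simulate_landscape(SimulationConfig(seed=1, raster_cellsize_deg=0.5))
        b = simulate_landscape(SimulationConfig(seed=2, raster_cellsize_deg=0.5))
        assert not np.array_equal(a.rasters["Elev"].values, b.rasters["Elev"].values)

    def test_zero_variance_field_is_constant(self):
        cfg = SimulationConfig(seed=1, raster_cellsize_deg=0.5)
        cfg.raster_fields["Temp"].scale = 0.0
        land = simulate_landscape(cfg)
        assert np.ptp(land.rasters["Temp"].values) == 0.0

    def test_configured_cross_correlations_emerge(self):
        cfg = SimulationConfig(
            seed=3, raster_cellsize_deg=0.1, temp_rain_correlation=0.8
        )
        land = simulate_landscape(cfg)
        r = np.corrcoef(
            land.rasters["Temp"].values.ravel(), land.rasters["Rain"].values.ravel()
        )[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_rasters_round_trip_through_ascii_grid(self, synthetic_dataset):
        outdir, _ = synthetic_dataset
        r = read_ascii_grid(outdir / "Elev.asc")
        land = simulate_landscape(
            SimulationConfig(seed=11, n_species=10, raster_cellsize_deg=0.5)
        )
        np.testing.assert_allclose(r.values, land.rasters["Elev"].values, rtol=1e-6)


class TestSpeciesHistories:
    def test_areas_nested_and_probabilities_valid(self):
        cfg = SimulationConfig(seed=21, n_species=15)
        hist = simulate_species_histories(cfg, simulate_landscape(cfg))
        a = hist.truth.areas
        assert (a["area_hol_km2"] >= a["area_hist_km2"] - 1e-6).all()
        assert (a["area_hist_km2"] >= a["area_mod_km2"] - 1e-6).all()
        assert a[["y_pre1900", "y_post1900"]].stack().between(0, 1).all()
        assert ((a["y_pre1900"] + a["y_post1900"]) <= 1 + 1e-9).all()

    def test_mass_effect_produces_positive_rank_correlation(self):
        # across independent faunas, heavier species lose more range
        rhos = []
        for seed in range(12):
            cfg = SimulationConfig(seed=seed, n_species=25, brownian_sigma2=0.1)
            h = simulate_species_histories(cfg, simulate_landscape(cfg))
            t = h.traits.table
            loss = (h.truth.areas["y_pre1900"] + h.truth.areas["y_post1900"])
            rhos.append(stats.spearmanr(np.log10(t["body_mass_kg"]), loss).statistic)
        assert np.mean(rhos) > 0.3

    def test_no_effects_no_noise_gives_uniform_contraction(self):
        cfg = SimulationConfig(
            seed=2, n_species=10, beta_mass_pre=0.0, beta_trophic_pre=0.0,
            beta_mass_post=0.0, beta_trophic_post=0.0, brownian_sigma2=0.0,
        )
        h = simulate_species_histories(cfg, simulate_landscape(cfg))
        base = 1 / (1 + np.exp(1.7))
        inland = h.truth.areas["y_pre1900"]
        # discs clipped by the border can deviate; all others hit the base rate
        assert np.median(np.abs(inland - base)) < 0.02

    def test_lambda_zero_residuals_uncorrelated_with_phylogeny(self):
        # under a star-structured truth the residual similarity should not
        # track phylogenetic covariance (Mantel-type check)
        cors = []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, n_species=20, lambda_true=0.0, brownian_sigma2=0.5,
                beta_mass_pre=0.0, beta_trophic_pre=0.0,
            )
            h = simulate_species_histories(cfg, simulate_landscape(cfg))
            order = sorted(h.traits.table.index)
            C = tree_covariance(h.tree, taxa=order).to_numpy()
            y = h.truth.areas.loc[order, "y_pre1900"].to_numpy()
            eta = np.log(np.clip(y, 1e-6, 1 - 1e-6) / (1 - np.clip(y, 1e-6, 1 - 1e-6)))
            prod = np.outer(eta - eta.mean(), eta - eta.mean())
            iu = np.triu_indices(len(order), 1)
            cors.append(stats.pearsonr(C[iu], prod[iu]).statistic)
        assert abs(np.mean(cors)) < 0.1

    def test_tree_is_reproducible_and_unit_depth(self):
        t1 = simulate_tree(16, seed=7)
        t2 = simulate_tree(16, seed=7)
        assert t1.as_string("newick") == t2.as_string("newick")
        t1.calc_node_root_distances()
        depths = [l.root_distance for l in t1.leaf_node_iter()]
        assert max(depths) == pytest.approx(1.0, abs=0.05)


class TestLocalitySampling:
    def test_all_points_inside_true_range(self):
        cfg = SimulationConfig(seed=31, n_species=6, holocene_sites=(10, 15),
                               historical_sites=(5, 10))
        land = simulate_landscape(cfg)
        hist = simulate_species_histories(cfg, land)
        from shapely.geometry import Point

        records = sample_locality_records(hist, cfg)
        assert records
        for r in records:
            geom = hist.ranges_lonlat[r.species_id][r.period]
            assert geom.buffer(1e-9).covers(Point(r.lon, r.lat))

    def test_zero_intensity_species_fails_min_site_filter(self):
        from faunarange.io_core import filter_species_by_min_sites

        cfg = SimulationConfig(seed=31, n_species=5, holocene_sites=(0, 0),
                               historical_sites=(5, 5))
        land = simulate_landscape(cfg)
        hist = simulate_species_histories(cfg, land)
        records = sample_locality_records(hist, cfg)
        catalog = filter_species_by_min_sites(records, min_sites=10)
        assert catalog.included_species == []

    def test_reconstruction_gap_shrinks_with_more_sites(self):
        # reconstructed area from k points is <= truth, and the deficit
        # shrinks in expectation as sampling intensifies
        from faunarange.reconstruction import ReconstructionConfig, build_period_range

        deficits = {}
        for k in (5, 50):
            vals = []
            for seed in range(6):
                cfg = SimulationConfig(seed=seed, n_species=3,
                                       holocene_sites=(k, k), historical_sites=(0, 0))
                land = simulate_landscape(cfg)
                hist = simulate_species_histories(cfg, land)
                records = sample_locality_records(hist, cfg)
                rcfg = ReconstructionConfig(projection=land.projection)
                for sp in hist.ranges_lonlat:
                    true_geom = land.projection.project_geometry(
                        hist.ranges_lonlat[sp][TimePeriod.HOLOCENE]
                    )
                    baseline = land.projection.project_geometry(
                        hist.ranges_lonlat[sp][TimePeriod.MODERN]
                    )
                    pts = [r for r in records if r.species_id == sp
                           and r.period is TimePeriod.HOLOCENE]
                    rs = build_period_range(baseline, pts, land.border, rcfg)
                    vals.append(1 - min(rs.area_km2 / true_geom.area, 1.0))
            deficits[k] = np.mean(vals)
        assert 0 <= deficits[50] <= deficits[5] <= 1


class TestCellLossSimulation:
    def test_counts_and_probabilities_consistent(self):
        cfg = SimulationConfig(seed=9)
        cells, truth = simulate_cell_loss_table(cfg, n_cells=400)
        t = cells.table
        assert (t["n_lost"] + t["n_retained"] >= 1).all()
        assert set(truth) == {"intercept", *PREDICTORS}

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=9)
        a, _ = simulate_cell_loss_table(cfg, n_cells=50)
        b, _ = simulate_cell_loss_table(cfg, n_cells=50)
        pd.testing.assert_frame_equal(a.table, b.table)
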