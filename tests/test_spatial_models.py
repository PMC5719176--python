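"""Binomial GLM suite: closed forms, ranking, deviance explained."""

import warnings

import numpy as np
import pandas as pd
import pytest

from faunarange.grids import CellLossTable, make_grid
from faunarange.periods import TimePeriod
from faunarange.projection import EqualAreaProjection
from faunarange.rasters import Raster
from faunarange.reconstruction import BorderGeometry
from faunarange.spatial import (
    MODEL_SUITE,
    PREDICTORS,
    CellLossGLM,
    aggregate_predictors,
    run_model_suite,
)
from faunarange.synthetic import SimulationConfig, simulate_cell_loss_table
from shapely.geometry import box


class TestAggregatePredictors:
    @staticmethod
    def setup_case(values_fn, cellsize=0.25):
        proj = EqualAreaProjection(central_meridian=5.0)
        border = BorderGeometry(proj.project_geometry(box(0, 0, 10, 10)))
        grid = make_grid(border, 200.0)
        n = int(10 / cellsize)
        xs = (np.arange(n) + 0.5) * cellsize
        lon, lat = np.meshgrid(xs, xs[::-1])
        rasters = {
            p: Raster(values=values_fn(p, lon, lat), xll=0, yll=0, cellsize=cellsize)
            for p in PREDICTORS
        }
        ids = grid.cell_ids
        loss = CellLossTable(
            interval=(TimePeriod.HOLOCENE, TimePeriod.HISTORICAL),
            table=pd.DataFrame(
                {"n_old": 5, "n_lost": 1, "p_cell": 0.2, "analysed": True,
                 "row": 0, "col": 0, "x_min": 0.0, "y_min": 0.0},
                index=pd.Index(ids, name="cell_id"),
            ),
        )
        return rasters, grid, loss, proj

    def test_constant_raster_gives_constant_cells(self):
        rasters, grid, loss, proj = self.setup_case(lambda p, lon, lat: 7.0 * np.ones_like(lon))
        cells = aggregate_predictors(rasters, grid, loss, proj)
        assert (cells.table[list(PREDICTORS)] == 7.0).all().all()

    def test_linear_gradient_mean_matches_centroid(self):
        rasters, grid, loss, proj = self.setup_case(
            lambda p, lon, lat: 100.0 * lon, cellsize=0.1
        )
        cells = aggregate_predictors(rasters, grid, loss, proj, subsample=7)
        cid = cells.table.index[0]
        x0, y0 = grid.cell_origin(cid)
        cx, cy = x0 + grid.cell_size / 2, y0 + grid.cell_size / 2
        lon_c, _ = proj.inverse(cx, cy)
        assert cells.table.loc[cid, "Elev"] == pytest.approx(100.0 * lon_c, rel=0.01)

    def test_hole_in_raster_drops_cell(self):
        def values(p, lon, lat):
            v = np.ones_like(lon)
            v[(lon < 2) & (lat < 2)] = np.nan
            return v

        rasters, grid, loss, proj = self.setup_case(values)
        cells = aggregate_predictors(rasters, grid, loss, proj)
        assert len(cells.dropped) > 0
        assert len(cells.table) + len(cells.dropped) == len(loss.analysed)


class TestCellLossGLM:
    def test_two_group_slope_matches_logit_difference(self):
        tab = pd.DataFrame(
            {"x": [0.0, 0.0, 1.0, 1.0], "n_lost": [2, 2, 8, 8], "n_retained": [8, 8, 2, 2]},
            index=list("abcd"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = CellLossGLM(tab, ("x",), standardize=False).fit()
        expected = np.log(0.8 / 0.2) - np.log(0.2 / 0.8)
        assert res.params["x"] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(2.7726, abs=1e-4)

    def test_intercept_only_explains_nothing(self):
        tab = pd.DataFrame(
            {"n_lost": [3, 3, 3], "n_retained": [7, 7, 7]}, index=list("abc")
        )
        res = CellLossGLM(tab, ()).fit()
        assert res.deviance_explained == pytest.approx(0.0, abs=1e-12)

    def test_null_simulation_explains_little(self):
        rng = np.random.default_rng(12)
        n = 500
        tab = pd.DataFrame(
            {p: rng.standard_normal(n) for p in PREDICTORS}
            | {"n_lost": rng.binomial(20, 0.3, n)},
            index=[f"c{i}" for i in range(n)],
        )
        tab["n_retained"] = 20 - tab["n_lost"]
        res = CellLossGLM(tab, PREDICTORS).fit()
        assert res.deviance_explained < 0.02

    def test_standardized_and_raw_coefficients_agree(self):
        cfg = SimulationConfig(seed=4)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=300)
        res = CellLossGLM(cells.table, ("Elev", "HFI")).fit()
        raw = CellLossGLM(cells.table, ("Elev", "HFI"), standardize=False).fit()
        np.testing.assert_allclose(
            res.params_raw[["Elev", "HFI"]], raw.params[["Elev", "HFI"]], rtol=1e-5
        )

    def test_too_few_cells_rejected(self):
        tab = pd.DataFrame({"x": [0, 1], "n_lost": [1, 1], "n_retained": [1, 1]})
        with pytest.raises(ValueError, match="cells"):
            CellLossGLM(tab, ("x",))

    def test_empirical_logit_mode_runs(self):
        cfg = SimulationConfig(seed=4)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=200)
        res = CellLossGLM(cells.table, ("Elev",), response="empirical_logit").fit()
        assert np.isfinite(res.llf)
        assert 0.0 <= res.deviance_explained <= 1.0


class TestModelSuite:
    def test_suite_has_ten_models_with_expected_formulas(self):
        assert len(MODEL_SUITE) == 10
        assert MODEL_SUITE["a"] == PREDICTORS
        assert MODEL_SUITE["h"] == ("Elev",)
        assert MODEL_SUITE["i"] == ("HFI",)
        assert MODEL_SUITE["j"] == ("PET", "Rain")
        assert all(set(t) <= set(PREDICTORS) for t in MODEL_SUITE.values())

    def test_deviance_explained_monotone_on_nested_chain(self):
        cfg = SimulationConfig(seed=8)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=400)
        chain = [("Elev",), ("Elev", "HFI"), ("Elev", "HFI", "Rain"), PREDICTORS]
        devs = [CellLossGLM(cells.table, t).fit().deviance_explained for t in chain]
        assert devs == sorted(devs)

    def test_permuting_cells_leaves_coefficients_unchanged(self):
        cfg = SimulationConfig(seed=2)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=200)
        res1 = CellLossGLM(cells.table, PREDICTORS).fit()
        rng = np.random.default_rng(0)
        shuffled = cells.table.iloc[rng.permutation(len(cells.table))]
        res2 = CellLossGLM(shuffled, PREDICTORS).fit()
        np.testing.assert_allclose(res1.params, res2.params, rtol=1e-8)

    def test_single_formula_suite_delta_zero(self):
        cfg = SimulationConfig(seed=2)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=100)
        rk = run_model_suite(cells, suite={"h": ("Elev",)})
        assert rk.table.loc["h", "dAICC"] == 0.0

    def test_full_suite_ranks_and_reports_deviance(self):
        cfg = SimulationConfig(seed=6)
        cells, _ = simulate_cell_loss_table(cfg, n_cells=300)
        rk = run_model_suite(cells)
        assert len(rk.table) == 10
        assert rk.table["dAICC"].iloc[0] == 0.0
        assert rk.table["pct_deviance_explained"].between(0, 1).all()
        # the generating model uses all six predictors: the full model
        # should explain at least as much deviance as any submodel
        assert (
            rk.table.loc["a", "pct_deviance_explained"]
            >= rk.table["pct_deviance_explained"].max() - 1e-12
        )

    def test_data_from_elevation_only_supports_h_or_superset(self):
        cfg = SimulationConfig(
            seed=13,
            cell_betas={"AET": 0.0, "Elev": -1.2, "HFI": 0.0, "PET": 0.0,
                        "Rain": 0.0, "Temp": 0.0},
        )
        cells, _ = simulate_cell_loss_table(cfg, n_cells=200)
        rk = run_model_suite(cells)
        supported_terms = [MODEL_SUITE[m] for m in rk.supported]
        assert any("Elev" in terms for terms in supported_terms)
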