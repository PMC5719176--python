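"""Synthetic study systems with recorded ground truth.

The generator emulates the structure of the empirical study system: a
bounded study region with six smooth, cross-correlated environmental
surfaces; a fauna of ~34 species on a birth-death phylogeny whose range
contractions are driven by body mass and trophic level with
phylogenetically correlated residuals; nested true ranges across the
three periods; presence-only locality sampling of the two older
periods; and per-cell loss counts driven by known logistic coefficients
on the six predictors.  Every stochastic draw descends from a single
seed through fixed substreams, and every ground-truth quantity is
recorded so that recovery tests can compare pipeline estimates against
what was simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon, box, mapping

from .io_core import LocalityRecord, TraitTable, write_geojson, write_locality_table
from .periods import TimePeriod
from .phylo import scale_lambda, tree_covariance
from .projection import EqualAreaProjection
from .rasters import Raster, write_ascii_grid
from .reconstruction import BorderGeometry
from .spatial import PREDICTORS

# substream offsets off the global seed
_SUB = {"landscape": 1, "tree": 2, "traits": 3, "ranges": 4, "sampling": 5, "cells": 6}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _SUB[component]])


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class RasterFieldSpec:
    """Mean/scale of one predictor surface in its physical units."""

    mean: float
    scale: float
    floor: float | None = None


@dataclass
class SimulationConfig:
    """Conditions of a synthetic study system.

    Defaults mirror the empirical setting: 34 species, 10-111 Holocene
    sites and 5-249 historical sites per species, body masses spanning
    ~0.25-3300 kg, a mass/trophic-driven pre-1900 contraction with
    Brownian residuals, a weakly structured post-1900 contraction, and
    per-cell loss odds rising with human footprint and temperature and
    falling with elevation, rainfall and PET.
    """

    seed: int = 0
    n_species: int = 34
    # study-region border, WGS84 degrees (a China-sized quadrangle)
    lon_min: float = 90.0
    lon_max: float = 120.0
    lat_min: float = 20.0
    lat_max: float = 45.0
    # locality sampling intensity per species (inclusive ranges)
    holocene_sites: tuple[int, int] = (10, 111)
    historical_sites: tuple[int, int] = (5, 249)
    elevation_sampling_bias: float = 0.0  # >0 biases sites toward low elevation
    # traits
    log10_mass_range: tuple[float, float] = (-0.6, 3.5)
    trophic_probs: tuple[float, float, float] = (0.5, 0.2, 0.3)
    # era contraction model on the logit scale (mass centred, trophic - 2)
    beta0_pre: float = -1.7
    beta_mass_pre: float = 0.8
    beta_trophic_pre: float = -0.5
    beta0_post: float = -2.2
    beta_mass_post: float = 0.0
    beta_trophic_post: float = 0.3
    brownian_sigma2: float = 0.4  # residual variance at unit tree depth
    lambda_true: float = 1.0
    # true range geometry (equal-area km)
    range_radius_km: tuple[float, float] = (300.0, 900.0)
    # landscape rasters
    raster_cellsize_deg: float = 0.25
    raster_smooth_sigma: float = 6.0  # cells
    temp_rain_correlation: float = 0.8
    aet_pet_correlation: float = 0.8
    raster_fields: dict[str, RasterFieldSpec] = field(
        default_factory=lambda: {
            "Elev": RasterFieldSpec(1200.0, 900.0, floor=0.0),
            "HFI": RasterFieldSpec(25.0, 10.0, floor=0.0),
            "Rain": RasterFieldSpec(800.0, 350.0, floor=0.0),
            "Temp": RasterFieldSpec(10.0, 8.0),
            "AET": RasterFieldSpec(550.0, 180.0, floor=0.0),
            "PET": RasterFieldSpec(800.0, 220.0, floor=0.0),
        }
    )
    # per-cell loss model (logit scale, standardized predictors)
    cell_beta0: float = -1.0
    cell_betas: dict[str, float] = field(
        default_factory=lambda: {
            "AET": 0.6, "Elev": -0.8, "HFI": 0.9, "PET": -0.5, "Rain": -0.4, "Temp": 0.5,
        }
    )

    def projection(self) -> EqualAreaProjection:
        return EqualAreaProjection(central_meridian=(self.lon_min + self.lon_max) / 2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["raster_fields"] = {k: dataclasses.asdict(v) for k, v in self.raster_fields.items()}
        return d


@dataclass
class Landscape:
    border_lonlat: Polygon
    border: BorderGeometry  # projected, km
    rasters: dict[str, Raster]  # geographic grids
    projection: EqualAreaProjection


@dataclass
class TruthRecord:
    """Ground truth of one simulated system, for recovery tests."""

    config: SimulationConfig
    areas: pd.DataFrame  # species x (area_hol/hist/mod_km2, y_pre1900, y_post1900)
    trait_betas: dict[str, float]
    cell_betas: dict[str, float] | None = None
    cell_probabilities: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "areas": self.areas.reset_index().to_dict(orient="list"),
            "trait_betas": self.trait_betas,
            "cell_betas": self.cell_betas,
            "cell_probabilities": (
                None if self.cell_probabilities is None
                else self.cell_probabilities.to_dict()
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


# ---------------------------------------------------------------------------
# landscape


def _correlated_fields(rng, shape, sigma, pairs, names):
    """Smooth unit-variance fields; listed pairs share a target correlation."""
    fields = {}
    raw = {n: ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
           for n in names}
    for n in names:
        f = raw[n]
        sd = f.std()
        fields[n] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    for a, b, rho in pairs:
        fields[b] = rho * fields[a] + np.sqrt(max(1 - rho**2, 0.0)) * fields[b]
        sd = fields[b].std()
        fields[b] = (fields[b] - fields[b].mean()) / (sd if sd > 0 else 1.0)
    return fields


def simulate_landscape(config: SimulationConfig) -> Landscape:
    """Border polygon plus six correlated predictor surfaces."""
    rng = _rng(config.seed, "landscape")
    proj = config.projection()
    border_lonlat = box(config.lon_min, config.lat_min, config.lon_max, config.lat_max)
    border = BorderGeometry(proj.project_geometry(border_lonlat))
    cs = config.raster_cellsize_deg
    ncols = int(round((config.lon_max - config.lon_min) / cs))
    nrows = int(round((config.lat_max - config.lat_min) / cs))
    z = _correlated_fields(
        rng,
        (nrows, ncols),
        config.raster_smooth_sigma,
        [("Temp", "Rain", config.temp_rain_correlation),
         ("AET", "PET", config.aet_pet_correlation)],
        list(PREDICTORS),
    )
    rasters = {}
    for name in PREDICTORS:
        spec = config.raster_fields[name]
        vals = spec.mean + spec.scale * z[name]
        if spec.floor is not None:
            vals = np.maximum(vals, spec.floor)
        rasters[name] = Raster(
            values=vals, xll=config.lon_min, yll=config.lat_min, cellsize=cs
        )
    return Landscape(
        border_lonlat=border_lonlat, border=border, rasters=rasters, projection=proj
    )


# ---------------------------------------------------------------------------
# species histories


def simulate_tree(n_tips: int, seed: int, min_terminal: float = 0.02) -> dendropy.Tree:
    """Pure-birth tree on ``n_tips`` tips, rescaled to unit root depth.

    Terminal branches are floored at ``min_terminal`` (relative to the
    unit depth) so that no two tips are effectively indistinguishable:
    a vanishing terminal branch makes the Brownian covariance singular,
    which neither real faunas nor the downstream GLS tolerate.
    """
    import random

    rng = _rng(seed, "tree")
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(int(rng.integers(2**31))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:03d}"
    tree.calc_node_root_distances()
    depth = max(l.root_distance for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is not None and leaf.edge.length < min_terminal:
            leaf.edge.length = min_terminal
    return tree


@dataclass
class SpeciesHistories:
    tree: dendropy.Tree
    traits: TraitTable  # with y_pre1900 / y_post1900 truth columns
    ranges_lonlat: dict[str, dict[TimePeriod, Polygon]]  # WGS84 true ranges
    truth: TruthRecord


def simulate_species_histories(
    config: SimulationConfig, landscape: Landscape
) -> SpeciesHistories:
    """True nested ranges, traits and phylogeny with recorded effects.

    Contraction per era is inverse-logit linear in centred log10 mass and
    trophic level plus a lambda-scaled Brownian deviate; ranges are discs
    in the equal-area plane eroded (scaled about their centre) to the
    era's area, so nesting holds by construction.
    """
    tree = simulate_tree(config.n_species, config.seed)
    species = sorted(t.label for t in tree.taxon_namespace)
    rng_t = _rng(config.seed, "traits")
    rng_r = _rng(config.seed, "ranges")
    n = config.n_species

    log_mass = rng_t.uniform(*config.log10_mass_range, size=n)
    trophic = rng_t.choice([1, 2, 3], size=n, p=config.trophic_probs)
    C = tree_covariance(tree, taxa=species).to_numpy()
    V = config.brownian_sigma2 * scale_lambda(C, config.lambda_true)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))
    dev_pre = L @ rng_t.standard_normal(n)
    dev_post = L @ rng_t.standard_normal(n)

    mass_c = log_mass - log_mass.mean()
    eta_pre = (config.beta0_pre + config.beta_mass_pre * mass_c
               + config.beta_trophic_pre * (trophic - 2) + dev_pre)
    eta_post = (config.beta0_post + config.beta_mass_post * mass_c
                + config.beta_trophic_post * (trophic - 2) + dev_post)
    p_pre = _invlogit(eta_pre)
    # the post-1900 interval can only remove what is left after 1900
    p_post = _invlogit(eta_post) * (1.0 - p_pre)

    border = landscape.border.polygon
    minx, miny, maxx, maxy = border.bounds
    ranges: dict[str, dict[TimePeriod, Polygon]] = {}
    rows = {}
    for i, sp in enumerate(species):
        r_hol = rng_r.uniform(*config.range_radius_km)
        cx = rng_r.uniform(minx + 0.2 * (maxx - minx), maxx - 0.2 * (maxx - minx))
        cy = rng_r.uniform(miny + 0.2 * (maxy - miny), maxy - 0.2 * (maxy - miny))
        disc_hol = Point(cx, cy).buffer(r_hol, quad_segs=64).intersection(border)
        disc_hist = (
            Point(cx, cy).buffer(r_hol * np.sqrt(max(1 - p_pre[i], 0.0)), quad_segs=64)
            .intersection(border)
        )
        frac_mod = max(1.0 - p_pre[i] - p_post[i], 0.0)
        disc_mod = Point(cx, cy).buffer(r_hol * np.sqrt(frac_mod), quad_segs=64).intersection(border)
        ranges[sp] = {
            TimePeriod.HOLOCENE: disc_hol,
            TimePeriod.HISTORICAL: disc_hist,
            TimePeriod.MODERN: disc_mod,
        }
        a_hol, a_hist, a_mod = disc_hol.area, disc_hist.area, disc_mod.area
        rows[sp] = {
            "area_hol_km2": a_hol,
            "area_hist_km2": a_hist,
            "area_mod_km2": a_mod,
            "y_pre1900": (a_hol - a_hist) / a_hol if a_hol > 0 else np.nan,
            "y_post1900": (a_hist - a_mod) / a_hol if a_hol > 0 else np.nan,
        }

    traits = TraitTable(
        table=pd.DataFrame(
            {
                "body_mass_kg": 10.0 ** log_mass,
                "trophic": trophic,
                "y_pre1900": [rows[s]["y_pre1900"] for s in species],
                "y_post1900": [rows[s]["y_post1900"] for s in species],
            },
            index=pd.Index(species, name="species"),
        )
    )
    truth = TruthRecord(
        config=config,
        areas=pd.DataFrame.from_dict(rows, orient="index").rename_axis("species"),
        trait_betas={
            "beta0_pre": config.beta0_pre,
            "beta_mass_pre": config.beta_mass_pre,
            "beta_trophic_pre": config.beta_trophic_pre,
            "beta0_post": config.beta0_post,
            "beta_mass_post": config.beta_mass_post,
            "beta_trophic_post": config.beta_trophic_post,
        },
    )
    return SpeciesHistories(tree=tree, traits=traits, ranges_lonlat=_unproject(ranges, landscape),
                            truth=truth)


def _unproject(ranges, landscape: Landscape):
    out = {}
    for sp, by_period in ranges.items():
        out[sp] = {
            per: landscape.projection.unproject_geometry(geom)
            for per, geom in by_period.items()
        }
    return out


# ---------------------------------------------------------------------------
# locality sampling


def _sample_points_in(geom, n: int, rng, landscape: Landscape | None = None,
                      bias: float = 0.0) -> list[tuple[float, float]]:
    """Uniform (optionally low-elevation-biased) points inside a polygon.

    Rejection sampling in the polygon's bounding box; with ``bias`` > 0
    a candidate at relative elevation z in [0, 1] is kept with
    probability exp(-bias * z), mimicking accessibility bias in
    archaeological sampling.
    """
    if geom.is_empty or geom.area <= 0 or n <= 0:
        return []
    minx, miny, maxx, maxy = geom.bounds
    elev = landscape.rasters["Elev"] if (landscape and bias > 0) else None
    erange = None
    if elev is not None:
        lo, hi = np.nanmin(elev.values), np.nanmax(elev.values)
        erange = (lo, max(hi - lo, 1e-9))
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n and attempts < 10000 * n:
        attempts += 1
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not geom.covers(Point(x, y)):
            continue
        if elev is not None:
            e = elev.sample(x, y)
            if np.isfinite(e):
                z = (float(e) - erange[0]) / erange[1]
                if rng.uniform() > np.exp(-bias * z):
                    continue
        pts.append((x, y))
    return pts


def sample_locality_records(
    histories: SpeciesHistories,
    config: SimulationConfig,
    landscape: Landscape | None = None,
) -> list[LocalityRecord]:
    """Presence-only locality records for the two pre-modern periods.

    Per species, the number of distinct sites per era is drawn from the
    configured intensity range and points are sampled inside the true
    era range (WGS84).
    """
    rng = _rng(config.seed, "sampling")
    records: list[LocalityRecord] = []
    for sp in sorted(histories.ranges_lonlat):
        for period, (lo, hi) in (
            (TimePeriod.HOLOCENE, config.holocene_sites),
            (TimePeriod.HISTORICAL, config.historical_sites),
        ):
            n_sites = int(rng.integers(lo, hi + 1))
            geom = histories.ranges_lonlat[sp][period]
            for j, (x, y) in enumerate(
                _sample_points_in(geom, n_sites, rng, landscape,
                                  config.elevation_sampling_bias)
            ):
                records.append(
                    LocalityRecord(
                        species_id=sp,
                        lon=float(x),
                        lat=float(y),
                        period=period,
                        site_id=f"{sp}_{period.value[:4]}_{j:04d}",
                        source="synthetic",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# per-cell loss counts with known coefficients


def simulate_cell_loss_table(
    config: SimulationConfig,
    n_cells: int = 500,
    mean_richness: float = 20.0,
    seed: int | None = None,
):
    """Cell predictor table with binomial losses from known coefficients.

    Standardized predictors are drawn with the configured Temp-Rain and
    AET-PET correlations; each cell's older-period richness is
    1 + Poisson(mean_richness - 1) and its losses are binomial with
    logit-linear probability.  Returns ``(CellPredictorTable, truth)``
    where truth maps each predictor to its simulated coefficient.
    """
    from .spatial import CellPredictorTable

    rng = _rng(config.seed if seed is None else seed, "cells")
    z = {p: rng.standard_normal(n_cells) for p in PREDICTORS}
    for a, b, rho in (
        ("Temp", "Rain", config.temp_rain_correlation),
        ("AET", "PET", config.aet_pet_correlation),
    ):
        z[b] = rho * z[a] + np.sqrt(max(1 - rho**2, 0.0)) * z[b]
    eta = config.cell_beta0 + sum(config.cell_betas[p] * z[p] for p in PREDICTORS)
    prob = _invlogit(eta)
    n_old = 1 + rng.poisson(max(mean_richness - 1.0, 0.0), size=n_cells)
    n_lost = rng.binomial(n_old, prob)
    table = pd.DataFrame(
        {**{p: z[p] for p in PREDICTORS}, "n_lost": n_lost, "n_retained": n_old - n_lost},
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    truth = {"intercept": config.cell_beta0, **config.cell_betas}
    return CellPredictorTable(table=table), truth


# ---------------------------------------------------------------------------
# full dataset emission in the pipeline's input formats


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> TruthRecord:
    """Write a complete synthetic input set plus ``truth.json``.

    Emits the exact formats the readers consume: ``localities.csv``,
    ``modern_ranges.geojson``, ``border.geojson``, ``traits.csv``,
    ``tree.nwk`` and six ``*.asc`` predictor grids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = simulate_landscape(config)
    histories = simulate_species_histories(config, landscape)
    records = sample_locality_records(histories, config, landscape)

    write_locality_table(records, outdir / "localities.csv")
    write_geojson(
        {sp: by[TimePeriod.MODERN] for sp, by in histories.ranges_lonlat.items()},
        outdir / "modern_ranges.geojson",
    )
    with (outdir / "border.geojson").open("w") as fh:
        json.dump(
            {"type": "Feature", "properties": {"name": "study region"},
             "geometry": mapping(landscape.border_lonlat)},
            fh,
        )
    histories.traits.table.reset_index().to_csv(outdir / "traits.csv", index=False)
    histories.tree.write(path=str(outdir / "tree.nwk"), schema="newick",
                         suppress_rooting=True)
    for name, raster in landscape.rasters.items():
        write_ascii_grid(raster, outdir / f"{name}.asc")
    histories.truth.to_json(outdir / "truth.json")
    return histories.truth
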