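"""Configuration-driven orchestration of the full analysis chain.

Stages (in order): read and validate inputs; reconstruct the cumulative
three-period ranges per species; grid the region and compute per-cell
species loss; fit the trait (PGLS) suite on the per-species loss
fractions; fit the spatial binomial GLM suite on the per-cell counts;
write report tables and an aggregate summary.  Every stage is a pure
function of the config and inputs; the run manifest records the config
and SHA-256 checksums of all inputs and outputs so reruns can be
verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_core
from .areas import aggregate_summary, area_table_from_ranges
from .grids import cell_proportion_lost, make_grid, presence_matrix
from .io_core import read_locality_table, read_range_polygons, read_traits_and_tree
from .periods import TimePeriod
from .pgls import run_trait_suite
from .projection import EqualAreaProjection
from .rasters import read_ascii_grid
from .reconstruction import BorderGeometry, ReconstructionConfig, build_species_ranges
from .spatial import PREDICTORS, aggregate_predictors, run_model_suite

logger = logging.getLogger(__name__)

STAGES = ("build-ranges", "grid", "fit-traits", "fit-spatial", "report")


class ConfigError(ValueError):
    """The pipeline configuration failed schema validation."""


@dataclass
class PipelineConfig:
    """Validated paths and options for one pipeline run."""

    localities: str
    border: str
    modern_ranges: str
    outdir: str
    extinct_parts: str | None = None
    traits: str | None = None
    tree: str | None = None
    rasters: dict[str, str] = field(default_factory=dict)  # predictor -> path
    central_meridian: float | None = None  # default: border centroid longitude
    epsilon_fraction: float = 1e-6
    min_sites: int = 10
    cell_size_km: float = 100.0
    lambda_mode: str = "ml"
    glm_response: str = "binomial"
    criterion: str = "aicc"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        required = [n for n, f in fields.items()
                    if f.default is dataclasses.MISSING
                    and f.default_factory is dataclasses.MISSING]
        missing = [n for n in required if n not in raw]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        cfg = cls(**raw)
        if cfg.min_sites < 1:
            raise ConfigError("min_sites must be >= 1")
        if cfg.cell_size_km <= 0:
            raise ConfigError("cell_size_km must be positive")
        if cfg.glm_response not in ("binomial", "empirical_logit"):
            raise ConfigError("glm_response must be 'binomial' or 'empirical_logit'")
        if cfg.rasters and set(cfg.rasters) != set(PREDICTORS):
            raise ConfigError(
                f"rasters must supply exactly {sorted(PREDICTORS)}, "
                f"got {sorted(cfg.rasters)}"
            )
        for name in ("localities", "border", "modern_ranges"):
            if not Path(getattr(cfg, name)).exists():
                raise ConfigError(f"{name} path does not exist: {getattr(cfg, name)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineReport:
    outdir: Path
    area_table: pd.DataFrame | None = None
    trait_rankings: dict[str, pd.DataFrame] = field(default_factory=dict)
    spatial_rankings: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> PipelineReport:
    """Execute the requested stages; halt with the stage name on failure."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(outdir=outdir)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": list(stages),
                      "inputs": {}, "outputs": {}}
    stage = "read-inputs"
    try:
        border_geoms = io_core.read_geojson(config.border)
        border_lonlat = next(iter(border_geoms.values()))
        cm = (config.central_meridian if config.central_meridian is not None
              else float(border_lonlat.centroid.x))
        projection = EqualAreaProjection(central_meridian=cm)
        border = BorderGeometry(projection.project_geometry(border_lonlat))
        recon_cfg = ReconstructionConfig(
            projection=projection, epsilon_fraction=config.epsilon_fraction
        )
        loc = read_locality_table(config.localities, border_lonlat)
        catalog = io_core.filter_species_by_min_sites(loc.records, config.min_sites)
        polys = read_range_polygons(config.modern_ranges, border_lonlat, config.extinct_parts)
        for name in ("localities", "border", "modern_ranges"):
            manifest["inputs"][name] = _sha256(Path(getattr(config, name)))

        ranges = None
        if "build-ranges" in stages:
            stage = "build-ranges"
            ranges = {}
            for sp in catalog.included_species:
                if sp not in polys.modern:
                    raise ValueError(f"included species {sp!r} has no modern range polygon")
                recs = [r for r in loc.records if r.species_id == sp]
                ranges[sp] = build_species_ranges(
                    sp,
                    polys.modern[sp],
                    [r for r in recs if r.period is TimePeriod.HISTORICAL],
                    [r for r in recs if r.period is TimePeriod.HOLOCENE],
                    border,
                    recon_cfg,
                    extinct_part=polys.extinct_parts.get(sp),
                )
            report.area_table = area_table_from_ranges(ranges)
            report.area_table.to_csv(outdir / "areas.csv")
            for sp, by_period in ranges.items():
                io_core.write_geojson(
                    {f"{sp}:{per.value}": projection.unproject_geometry(rs.geometry)
                     for per, rs in by_period.items()},
                    outdir / f"range_{sp}.geojson",
                )

        loss_tables = {}
        grid = None
        if "grid" in stages and ranges is not None:
            stage = "grid"
            grid = make_grid(border, config.cell_size_km, crs_tag=projection.crs_tag)
            pres = {per: presence_matrix(ranges, grid, per) for per in TimePeriod}
            for tag, old_p, new_p in (
                ("pre1900", TimePeriod.HOLOCENE, TimePeriod.HISTORICAL),
                ("post1900", TimePeriod.HISTORICAL, TimePeriod.MODERN),
                ("hol_mod", TimePeriod.HOLOCENE, TimePeriod.MODERN),
            ):
                recs = [r for r in loc.records if r.period is old_p]
                tab = cell_proportion_lost(pres[old_p], pres[new_p], recs, grid, projection)
                loss_tables[tag] = tab
                tab.table.to_csv(outdir / f"cell_loss_{tag}.csv")

        if "fit-traits" in stages and report.area_table is not None:
            stage = "fit-traits"
            if not (config.traits and config.tree):
                raise ConfigError("fit-traits requested but traits/tree paths missing")
            traits, tree = read_traits_and_tree(config.traits, config.tree, catalog)
            at = report.area_table
            t = traits.table.copy()
            t["y_pre1900"] = at.loc[t.index, "p_lost_hol_hist"]
            t["y_post1900"] = (
                (at.loc[t.index, "area_hist_km2"] - at.loc[t.index, "area_mod_km2"])
                / at.loc[t.index, "area_hol_km2"]
            )
            traits = io_core.TraitTable(table=t)
            for era, resp in (("pre1900", "y_pre1900"), ("post1900", "y_post1900")):
                ranking = run_trait_suite(traits, tree, resp, lambda_mode=config.lambda_mode)
                report.trait_rankings[era] = ranking.table
                ranking.table.to_csv(outdir / f"trait_models_{era}.csv")

        if "fit-spatial" in stages and loss_tables:
            stage = "fit-spatial"
            if not config.rasters:
                raise ConfigError("fit-spatial requested but predictor rasters missing")
            rasters = {name: read_ascii_grid(path) for name, path in config.rasters.items()}
            for era in ("pre1900", "post1900"):
                cells = aggregate_predictors(rasters, grid, loss_tables[era], projection)
                ranking = run_model_suite(
                    cells, response=config.glm_response, criterion=config.criterion
                )
                report.spatial_rankings[era] = ranking.table
                ranking.table.to_csv(outdir / f"spatial_models_{era}.csv")

        if "report" in stages and report.area_table is not None:
            stage = "report"
            summ = aggregate_summary(report.area_table)
            report.summary = dataclasses.asdict(summ)
            (outdir / "summary.json").write_text(json.dumps(report.summary, indent=1))

        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.name != "run_manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        report.manifest = manifest
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report
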