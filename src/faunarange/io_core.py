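"""Readers, validators and filters for the pipeline's inputs.

Inputs are plain, interchange-friendly formats: locality tables as CSV
(``species,lon,lat,period,site_id,source``, WGS84 decimal degrees),
polygons as GeoJSON, traits as CSV, phylogenies as Newick and predictor
surfaces as ESRI ASCII grids.  Everything is validated into the typed
data model used downstream; malformed rows are collected rather than
fatal unless the whole table fails.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from shapely.geometry import Point, shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .periods import TimePeriod

logger = logging.getLogger(__name__)

LOCALITY_COLUMNS = ("species", "lon", "lat", "period", "site_id", "source")


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


@dataclass(frozen=True)
class LocalityRecord:
    """One dated, georeferenced occurrence of a species.

    Only the two pre-modern periods arrive as points; modern ranges are
    polygons from expert-drawn maps, not locality records.
    """

    species_id: str
    lon: float
    lat: float
    period: TimePeriod
    site_id: str
    source: str = ""

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if self.period is TimePeriod.MODERN:
            raise ValueError("modern occurrences arrive as polygons, not points")

    @property
    def point(self) -> Point:
        return Point(self.lon, self.lat)


@dataclass
class RejectedRow:
    row_number: int
    reason: str
    raw: dict


@dataclass
class LocalityReadResult:
    records: list[LocalityRecord]
    rejected: list[RejectedRow] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class SpeciesCatalog:
    """Per-species inclusion flags under the minimum-site rule.

    A species enters the comparative analysis only when it is recorded
    from at least ``min_sites`` distinct Holocene sites (default 10):
    sparser species cannot support a reconstructed range polygon that is
    robust to sampling noise.
    """

    table: pd.DataFrame  # index species_id; columns: display_name, n_holocene_sites, included
    min_sites: int

    @property
    def included_species(self) -> list[str]:
        return sorted(self.table.index[self.table["included"]])

    @property
    def excluded_species(self) -> list[str]:
        return sorted(self.table.index[~self.table["included"]])

    def is_included(self, species_id: str) -> bool:
        return bool(self.table.loc[species_id, "included"])


def normalize_species_id(name: str) -> str:
    """Case-insensitive id with spaces/underscores unified.

    Newick labels conventionally use underscores where CSV tables use
    spaces; both map to one canonical id.
    """
    return "_".join(name.strip().lower().replace("_", " ").split())


def read_locality_table(
    path: str | Path, border: BaseGeometry | None = None
) -> LocalityReadResult:
    """Read and validate a locality CSV.

    Rows with unparseable coordinates, out-of-range coordinates, unknown
    periods or (when ``border`` is given) points strictly outside the
    study-region border are rejected with a reason; points exactly on the
    border boundary count as inside.  Raises ``SchemaError`` if required
    columns are missing, and ``ValueError`` if every row fails.
    """
    path = Path(path)
    records: list[LocalityRecord] = []
    rejected: list[RejectedRow] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        missing = [c for c in LOCALITY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        for i, raw in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in raw.items() if k}
            try:
                lon, lat = float(row["lon"]), float(row["lat"])
            except ValueError:
                rejected.append(RejectedRow(i, "unparseable coordinate", row))
                continue
            try:
                period = TimePeriod.parse(row["period"])
                rec = LocalityRecord(
                    species_id=normalize_species_id(row["species"]),
                    lon=lon,
                    lat=lat,
                    period=period,
                    site_id=row["site_id"],
                    source=row.get("source", ""),
                )
            except ValueError as exc:
                reason = str(exc)
                if "out of range" in reason:
                    reason = "coordinate out of range"
                rejected.append(RejectedRow(i, reason, row))
                continue
            if border is not None and not _covers(border, rec.point):
                rejected.append(RejectedRow(i, "outside border", row))
                continue
            records.append(rec)
    if rejected and not records:
        raise ValueError(f"{path}: all {len(rejected)} rows failed validation")
    for r in rejected:
        logger.warning("%s row %d rejected: %s", path.name, r.row_number, r.reason)
    return LocalityReadResult(records=records, rejected=rejected)


def _covers(border: BaseGeometry, point: Point) -> bool:
    # covers() (not contains) so boundary points count as inside
    return border.covers(point)


def write_locality_table(records: list[LocalityRecord], path: str | Path) -> None:
    """Write records back to the canonical CSV layout (round-trip safe)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOCALITY_COLUMNS)
        for r in records:
            writer.writerow(
                [r.species_id, repr(r.lon), repr(r.lat), r.period.value, r.site_id, r.source]
            )


def filter_species_by_min_sites(
    records: list[LocalityRecord], min_sites: int = 10
) -> SpeciesCatalog:
    """Flag species recorded from >= ``min_sites`` distinct Holocene sites.

    Sites, not specimens, are counted: duplicate records of a species at
    one site count once.  Idempotent and monotone in ``min_sites``.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if not records:
        logger.warning("empty record list: empty catalog")
    sites: dict[str, set[str]] = {}
    for r in records:
        sites.setdefault(r.species_id, set())
        if r.period is TimePeriod.HOLOCENE:
            sites[r.species_id].add(r.site_id)
    ids = sorted(sites)
    table = pd.DataFrame(
        {
            "display_name": [s.replace("_", " ").capitalize() for s in ids],
            "n_holocene_sites": [len(sites[s]) for s in ids],
        },
        index=pd.Index(ids, name="species_id"),
    )
    table["included"] = table["n_holocene_sites"] >= min_sites
    return SpeciesCatalog(table=table, min_sites=min_sites)


# ---------------------------------------------------------------------------
# polygons


def read_geojson(path: str | Path) -> dict[str, BaseGeometry]:
    """GeoJSON FeatureCollection -> {feature id/species: geometry}.

    The feature key is taken from properties ``species``/``species_id``/
    ``id``/``name`` (first found), else the feature index.  Invalid
    geometries are repaired with ``make_valid``.
    """
    with Path(path).open() as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out: dict[str, BaseGeometry] = {}
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        key = next(
            (props[k] for k in ("species", "species_id", "id", "name") if k in props),
            str(i),
        )
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            if not geom.is_valid:
                raise ValueError(f"{path}: unrepairable geometry for {key!r}")
        out[normalize_species_id(str(key))] = geom
    return out


def write_geojson(geoms: dict[str, BaseGeometry], path: str | Path, **props) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"species": key, **props},
            "geometry": mapping(geom),
        }
        for key, geom in sorted(geoms.items())
    ]
    with Path(path).open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class RangePolygonSet:
    """Modern baseline polygons plus any extinct-range parts carved out.

    Parts of expert range maps flagged as no-longer-occupied are removed
    from the modern layer but belong in the historical layer, so they are
    returned separately for merger there.
    """

    modern: dict[str, BaseGeometry]
    extinct_parts: dict[str, BaseGeometry]


def read_range_polygons(
    path: str | Path,
    border: BaseGeometry,
    extinct_parts_path: str | Path | None = None,
) -> RangePolygonSet:
    """Read modern range polygons, subtract extinct parts, clip to border."""
    polys = read_geojson(path)
    extinct = read_geojson(extinct_parts_path) if extinct_parts_path else {}
    modern: dict[str, BaseGeometry] = {}
    extinct_clipped: dict[str, BaseGeometry] = {}
    for sp, geom in polys.items():
        if sp in extinct:
            ext = extinct[sp].intersection(border)
            geom = geom.difference(extinct[sp])
            if not ext.is_empty:
                extinct_clipped[sp] = ext
        modern[sp] = geom.intersection(border)
    return RangePolygonSet(modern=modern, extinct_parts=extinct_clipped)


# ---------------------------------------------------------------------------
# traits and tree


@dataclass
class TraitTable:
    """Species-level predictors and responses for the comparative models."""

    table: pd.DataFrame  # index species_id; columns body_mass_kg, trophic [, y_*]

    def __post_init__(self):
        t = self.table
        if (t["body_mass_kg"] <= 0).any():
            bad = sorted(t.index[t["body_mass_kg"] <= 0])
            raise ValueError(f"non-positive body mass for {bad}")
        if not t["trophic"].isin([1, 2, 3]).all():
            bad = sorted(t.index[~t["trophic"].isin([1, 2, 3])])
            raise ValueError(
                f"trophic level must be 1 (herbivore), 2 (omnivore) or 3 "
                f"(carnivore); offending species: {bad}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.table.index)


def read_traits_and_tree(
    traits_path: str | Path,
    tree_path: str | Path,
    catalog: SpeciesCatalog | None = None,
) -> tuple[TraitTable, dendropy.Tree]:
    """Read the trait CSV and Newick tree, restrict both to included species.

    The tree is pruned to the included species; extra tips are logged.
    Included species missing from either source are a fatal error listing
    every missing id.
    """
    df = pd.read_csv(traits_path)
    required = {"species", "body_mass_kg", "trophic"}
    if not required <= set(df.columns):
        raise SchemaError(f"{traits_path}: missing columns {sorted(required - set(df.columns))}")
    df["species"] = df["species"].map(normalize_species_id)
    df = df.set_index("species")

    tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
    tip_map = {normalize_species_id(t.label): t for t in tree.taxon_namespace}

    wanted = (
        catalog.included_species if catalog is not None else sorted(df.index)
    )
    missing_traits = [s for s in wanted if s not in df.index]
    missing_tips = [s for s in wanted if s not in tip_map]
    if missing_traits or missing_tips:
        raise ValueError(
            f"included species missing from traits: {missing_traits}; "
            f"missing from tree: {missing_tips}"
        )
    extra = sorted(set(tip_map) - set(wanted))
    if extra:
        logger.info("pruning %d tree tips not in the analysis set: %s", len(extra), extra)
        tree.retain_taxa([tip_map[s] for s in wanted])
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_species_id(taxon.label)
    traits = TraitTable(table=df.loc[wanted])
    return traits, tree
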