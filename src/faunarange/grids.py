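"""Equal-area richness grids and per-cell species-loss tables.

A square grid (default 100 x 100 km) is laid over the projected border,
anchored at the lower-left corner of its bounding box; partial edge
cells are retained, cells that miss the border entirely are dropped.
Per period, a species is present in a cell when its range polygon
overlaps the cell with positive area.  Per interval, the proportion of
species lost in a cell is the share of the older period's occupants no
longer present in the newer period — computed only for cells that
actually contain a locality record of the older period, since cells
without older records cannot distinguish true absence from
non-sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .io_core import LocalityRecord
from .periods import TimePeriod
from .projection import EqualAreaProjection
from .reconstruction import BorderGeometry, RangeSet


@dataclass
class GridSpec:
    """A rectangular tiling of the projected study region.

    ``cells`` maps cell id ``"r{row}c{col}"`` to its box polygon; rows
    count from the south, columns from the west.
    """

    cell_size: float
    origin: tuple[float, float]
    n_rows: int
    n_cols: int
    crs_tag: str
    cells: dict[str, BaseGeometry] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.cells)

    def cell_origin(self, cell_id: str) -> tuple[float, float]:
        row, col = cell_id[1:].split("c")
        return (
            self.origin[0] + int(col) * self.cell_size,
            self.origin[1] + int(row) * self.cell_size,
        )


def make_grid(border: BorderGeometry, cell_size: float = 100.0, crs_tag: str = "") -> GridSpec:
    """Tile the border's projected bounding box with square cells.

    Cells not intersecting the border are dropped; partial edge cells
    are kept (ceiling tiling of the bounding box).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    minx, miny, maxx, maxy = border.polygon.bounds
    n_cols = max(1, math.ceil((maxx - minx) / cell_size - 1e-9))
    n_rows = max(1, math.ceil((maxy - miny) / cell_size - 1e-9))
    cells: dict[str, BaseGeometry] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            cell = box(
                minx + c * cell_size,
                miny + r * cell_size,
                minx + (c + 1) * cell_size,
                miny + (r + 1) * cell_size,
            )
            if cell.intersection(border.polygon).area > 0:
                cells[f"r{r}c{c}"] = cell
    return GridSpec(
        cell_size=cell_size,
        origin=(minx, miny),
        n_rows=n_rows,
        n_cols=n_cols,
        crs_tag=crs_tag,
        cells=cells,
    )


@dataclass
class PresenceMatrix:
    """Binary species x cell occupancy for one period."""

    period: TimePeriod
    matrix: pd.DataFrame  # index species, columns cell ids, values 0/1

    @property
    def richness(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)


def presence_matrix(
    ranges: dict[str, dict[TimePeriod, RangeSet]],
    grid: GridSpec,
    period: TimePeriod,
) -> PresenceMatrix:
    """Occupancy by positive-area overlap of range polygons with cells."""
    species = sorted(ranges)
    for sp in species:
        if period not in ranges[sp]:
            raise ValueError(f"species {sp!r} missing a {period.value} range layer")
    cell_ids = grid.cell_ids
    cell_geoms = [grid.cells[cid] for cid in cell_ids]
    tree = STRtree(cell_geoms)
    mat = np.zeros((len(species), len(cell_ids)), dtype=int)
    for i, sp in enumerate(species):
        geom = ranges[sp][period].geometry
        if geom.is_empty:
            continue
        for j in tree.query(geom):
            if geom.intersection(cell_geoms[j]).area > 0:
                mat[i, j] = 1
    return PresenceMatrix(
        period=period,
        matrix=pd.DataFrame(mat, index=species, columns=cell_ids),
    )


@dataclass
class CellLossTable:
    """Per-cell species loss for one interval, with the record filter."""

    interval: tuple[TimePeriod, TimePeriod]
    table: pd.DataFrame  # index cell_id; n_old, n_lost, p_cell, analysed

    @property
    def analysed(self) -> pd.DataFrame:
        return self.table[self.table["analysed"]]


def cell_proportion_lost(
    old: PresenceMatrix,
    new: PresenceMatrix,
    records: list[LocalityRecord],
    grid: GridSpec,
    projection: EqualAreaProjection | None = None,
) -> CellLossTable:
    """Proportion of the older period's occupants lost, per analysed cell.

    A cell is analysed only when it holds at least one locality record
    of the older period *and* at least one species in the older layer.
    ``records`` are WGS84 and are projected here (pass ``projection``
    matching the grid; default projection otherwise).
    """
    if list(old.matrix.index) != list(new.matrix.index):
        raise ValueError("presence matrices have different species sets")
    if list(old.matrix.columns) != list(new.matrix.columns):
        raise ValueError("presence matrices are on different grids")
    proj = projection or EqualAreaProjection()
    cell_ids = grid.cell_ids
    cell_geoms = [grid.cells[cid] for cid in cell_ids]
    tree = STRtree(cell_geoms)
    has_record = np.zeros(len(cell_ids), dtype=bool)
    for rec in records:
        x, y = proj.forward(rec.lon, rec.lat)
        p = Point(float(x), float(y))
        for j in tree.query(p, predicate="intersects"):
            has_record[j] = True
    n_old = old.matrix.to_numpy().sum(axis=0)
    lost = ((old.matrix.to_numpy() == 1) & (new.matrix.to_numpy() == 0)).sum(axis=0)
    analysed = has_record & (n_old > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cell = np.where(n_old > 0, lost / np.maximum(n_old, 1), np.nan)
    rows = []
    for j, cid in enumerate(cell_ids):
        x_min, y_min = grid.cell_origin(cid)
        row, col = cid[1:].split("c")
        rows.append(
            {
                "cell_id": cid,
                "row": int(row),
                "col": int(col),
                "x_min": x_min,
                "y_min": y_min,
                "n_old": int(n_old[j]),
                "n_lost": int(lost[j]),
                "p_cell": p_cell[j],
                "analysed": bool(analysed[j]),
            }
        )
    return CellLossTable(
        interval=(old.period, new.period),
        table=pd.DataFrame(rows).set_index("cell_id"),
    )


def empirical_logit(p: float | np.ndarray, n: int | np.ndarray, adjustment: float | None = None):
    """Empirical logit ln((p + a)/(1 - p + a)) with a = 0.5/n by default.

    The adjustment keeps proportions of 0 and 1 finite; it is exposed for
    sensitivity analyses.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("empirical logit undefined for n < 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    a = 0.5 / n if adjustment is None else adjustment
    out = np.log((p + a) / (1 - p + a))
    return float(out) if out.ndim == 0 else out
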