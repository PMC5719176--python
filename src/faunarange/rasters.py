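"""ESRI ASCII grid raster I/O.

Predictor surfaces (elevation, HFI, precipitation, temperature, AET, PET)
enter the pipeline as single-band rasters in the plain-text ESRI ASCII
grid format (``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``
header followed by rows, north to south).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class Raster:
    """A single-band raster: ``values[0, 0]`` is the north-west cell.

    ``xll``/``yll`` are the lower-left corner coordinates and ``cellsize``
    the square cell edge, all in the raster's own CRS units (degrees for
    geographic grids, km for projected ones).
    """

    values: np.ndarray  # 2-D float array, NaN where nodata
    xll: float
    yll: float
    cellsize: float
    crs_tag: str = "EPSG:4326"

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, shaped like ``values``."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell values at coordinates (x, y); NaN outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((y - self.yll) / self.cellsize).astype(int)
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out


def read_ascii_grid(path: str | Path, crs_tag: str = "EPSG:4326") -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
        values = np.loadtxt(fh, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        crs_tag=crs_tag,
    )


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    path = Path(path)
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, vals, fmt="%.8g")
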