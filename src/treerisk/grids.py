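"""Plain-text raster grids (ESRI ASCII grid dialect).

Reference layers (human footprint, climate, land/sea mask) are stored as
text grids — ``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``
header followed by rows of values, top row = northernmost — so the whole
pipeline stays free of binary formats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A regular lon/lat raster. ``values[0, :]`` is the northernmost row."""

    values: np.ndarray  # (nrows, ncols) float
    xll: float  # west edge, degrees
    yll: float  # south edge, degrees
    cellsize: float  # degrees
    nodata: float = NODATA

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def bounds(self):
        return (self.xll, self.yll, self.xll + self.ncols * self.cellsize, self.yll + self.nrows * self.cellsize)

    def cell_index(self, lons, lats):
        """Nearest-cell (row, col) for points; -1 where outside the grid."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        col = np.floor((lons - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lats - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def sample(self, lons, lats):
        """Nearest-cell values at points; NaN outside the grid or at nodata."""
        row, col = self.cell_index(lons, lats)
        out = np.full(np.shape(row), np.nan, dtype=float)
        inside = row >= 0
        vals = self.values[row[inside], col[inside]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[inside] = vals
        return out

    def cell_center(self, row, col):
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def write(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cellsize!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for r in range(self.nrows):
                fh.write(" ".join(repr(float(v)) for v in self.values[r]) + "\n")

    @classmethod
    def read(cls, path) -> "Grid":
        path = Path(path)
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        values = np.asarray(rows, dtype=float)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError(f"grid shape {values.shape} disagrees with header in {path}")
        return cls(
            values=values,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", NODATA),
        )
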