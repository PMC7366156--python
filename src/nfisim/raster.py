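"""Minimal planar raster container with ESRI ASCII grid serialization.

Rasters use a projected coordinate system in metres, cell-centre convention,
``data[0, 0]`` at the north-west corner (standard grid-file row order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster"]


@dataclass
class Raster:
    data: np.ndarray  # (nrows, ncols); row 0 = northernmost
    x0: float  # west edge (lower-left corner x)
    y0: float  # south edge (lower-left corner y)
    cell_size: float
    nodata: float = field(default=-9999.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) with ys ordered north to south, matching ``data`` rows."""
        xs = self.x0 + self.cell_size * (np.arange(self.ncols) + 0.5)
        ys = self.y0 + self.cell_size * (np.arange(self.nrows)[::-1] + 0.5)
        return xs, ys

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing the points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((y - self.y0) / self.cell_size).astype(int)
        if np.any((col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)):
            raise ValueError("point outside raster extent")
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell value at the given coordinates."""
        row, col = self.index_of(x, y)
        return self.data[row, col]

    @classmethod
    def from_south_up(cls, field_south_up: np.ndarray, x0: float, y0: float, cell_size: float) -> "Raster":
        """Build from an array whose row 0 is the southernmost row."""
        return cls(np.asarray(field_south_up)[::-1].copy(), x0, y0, cell_size)

    def to_ascii(self, path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        body = np.where(np.isnan(self.data), self.nodata, self.data)
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        return cls(data, meta["xllcorner"], meta["yllcorner"], meta["cellsize"], nodata)
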