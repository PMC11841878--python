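"""Lightweight single-band raster on a regular projected grid.

The package works entirely in projected coordinates with meter units; a
raster is a 2-D float array plus an origin, a cell size and an opaque CRS
tag.  Row 0 is the *top* row (north-up convention), so the cell (row, col)
has its center at::

    x = x_min + (col + 0.5) * resolution
    y = y_max - (row + 0.5) * resolution

Rasters round-trip through the ESRI ASCII grid format (plain text), which
every GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band north-up raster in a projected CRS (meter units)."""

    values: np.ndarray          # shape (n_rows, n_cols), row 0 = top
    x_min: float
    y_min: float
    resolution: float           # cell size, m
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.resolution

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        r = self.resolution
        return (self.x_min + (col + 0.5) * r, self.y_max - (row + 0.5) * r)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of all cell-center coordinates."""
        r = self.resolution
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * r
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * r
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing (x, y), half-open convention [x0, x0 + res)."""
        col = int(np.floor((x - self.x_min) / self.resolution))
        row = int(np.floor((self.y_max - y) / self.resolution))
        if y == self.y_min:          # bottom edge belongs to the last row
            row = self.n_rows - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x < self.x_max) and (self.y_min < y <= self.y_max)

    def copy_with(self, values: np.ndarray) -> "Raster":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Raster(values, self.x_min, self.y_min, self.resolution, self.crs)

    # ---- I/O ----------------------------------------------------------
    def write_ascii(self, path: str | Path, nodata: float = NODATA) -> None:
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x_min!r}\n"
            f"yllcorner {self.y_min!r}\n"
            f"cellsize {self.resolution!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path, crs: str = "local-meters") -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        return cls(vals, meta["xllcorner"], meta["yllcorner"], meta["cellsize"], crs)
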