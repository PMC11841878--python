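"""Moving-window TAO statistics on the 5-m analysis grid.

For every cell of the analysis grid, statistics of the TAOs falling
within a circular window centered on the cell: count density (per acre),
sum / mean / min / max / sample SD of heights, filtered to a minimum TAO
height.  The final habitat model uses three of these layers:

* ``density_ge60_5ac`` — density of TAOs >= 60 m within a 5-acre circle,
* ``sumht_ge50_5ac``   — sum of heights of TAOs >= 50 m within a 5-acre circle,
* ``sdht_ge50_5ac``    — SD of heights of TAOs >= 50 m within a 5-acre circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .raster import Raster
from .tao_detect import TAOSet

ACRE_M2 = 4046.8564224  # international acre in m^2

STATS = ("count_density", "sum", "sd", "min", "mean", "max")


def circle_radius_for_area(area_acres: float) -> float:
    """Radius (m) of the circle whose area is ``area_acres`` acres.

    1 acre -> 35.89 m, 5 acres -> 80.25 m (to 2 dp) — the radii of the
    1- and 5-acre moving windows.
    """
    if area_acres < 0:
        raise ValueError("area must be >= 0")
    return float(np.sqrt(area_acres * ACRE_M2 / np.pi))


@dataclass(frozen=True)
class GridSpec:
    """The analysis grid: origin, cell size (default 5 m), shape, CRS tag."""

    x_min: float
    y_min: float
    n_rows: int
    n_cols: int
    cell_size: float = 5.0
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")

    @classmethod
    def from_extent(cls, extent: tuple[float, float, float, float],
                    cell_size: float = 5.0, crs: str = "local-meters") -> "GridSpec":
        x0, y0, x1, y1 = extent
        return cls(x0, y0,
                   int(np.ceil((y1 - y0) / cell_size)),
                   int(np.ceil((x1 - x0) / cell_size)),
                   cell_size, crs)

    @classmethod
    def from_raster(cls, raster: Raster, cell_size: float = 5.0) -> "GridSpec":
        return cls.from_extent(
            (raster.x_min, raster.y_min, raster.x_max, raster.y_max),
            cell_size, raster.crs)

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    def cell_centers(self) -> np.ndarray:
        """(n_rows * n_cols, 2) array of centers, row-major from the top row."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X.ravel(), Y.ravel()])

    def empty_raster(self) -> Raster:
        return Raster(np.zeros((self.n_rows, self.n_cols)),
                      self.x_min, self.y_min, self.cell_size, self.crs)


def tao_window_stat(
    taos: TAOSet,
    grid: GridSpec,
    stat: str,
    height_min: float = 0.0,
    window_area_acres: float = 5.0,
) -> Raster:
    """One moving-window statistic layer.

    TAOs with height >= ``height_min`` and center distance <= the window
    radius (inclusive) contribute to each cell.  Density is count divided
    by the window area in *acres* (per-acre units whatever the window
    size).  SD is the sample (n-1) standard deviation, 0 when fewer than
    two trees; min/mean/max of an empty window are 0.
    """
    if stat not in STATS:
        raise ValueError(f"stat must be one of {STATS}")
    if window_area_acres <= 0:
        raise ValueError("window_area must be > 0")
    if taos.source.get("crs") and taos.source["crs"] != grid.crs:
        raise ValueError("TAO set and grid are in different CRS")
    radius = circle_radius_for_area(window_area_acres)
    keep = taos.height >= height_min
    xy = taos.coords()[keep]
    heights = taos.height[keep]
    out = np.zeros(grid.n_rows * grid.n_cols)
    if xy.shape[0] > 0:
        tree = cKDTree(xy)
        centers = grid.cell_centers()
        neighborhoods = tree.query_ball_point(centers, r=radius + 1e-9)
        for i, idx in enumerate(neighborhoods):
            if not idx:
                continue
            h = heights[idx]
            if stat == "count_density":
                out[i] = h.size / window_area_acres
            elif stat == "sum":
                out[i] = h.sum()
            elif stat == "sd":
                out[i] = h.std(ddof=1) if h.size > 1 else 0.0
            elif stat == "min":
                out[i] = h.min()
            elif stat == "mean":
                out[i] = h.mean()
            elif stat == "max":
                out[i] = h.max()
    return Raster(out.reshape(grid.n_rows, grid.n_cols),
                  grid.x_min, grid.y_min, grid.cell_size, grid.crs)


def tao_window_stat_bruteforce(
    taos: TAOSet, grid: GridSpec, stat: str,
    height_min: float = 0.0, window_area_acres: float = 5.0,
) -> Raster:
    """O(cells x TAOs) direct scan; independent oracle for tao_window_stat."""
    radius = circle_radius_for_area(window_area_acres)
    keep = taos.height >= height_min
    xs, ys, hs = taos.x[keep], taos.y[keep], taos.height[keep]
    out = np.zeros(grid.n_rows * grid.n_cols)
    for i, (cx, cy) in enumerate(grid.cell_centers()):
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        h = hs[d2 <= radius**2 + 1e-9 * radius]
        if h.size == 0:
            continue
        if stat == "count_density":
            out[i] = h.size / window_area_acres
        elif stat == "sum":
            out[i] = h.sum()
        elif stat == "sd":
            out[i] = h.std(ddof=1) if h.size > 1 else 0.0
        elif stat == "min":
            out[i] = h.min()
        elif stat == "mean":
            out[i] = h.mean()
        elif stat == "max":
            out[i] = h.max()
    return Raster(out.reshape(grid.n_rows, grid.n_cols),
                  grid.x_min, grid.y_min, grid.cell_size, grid.crs)


@dataclass
class CovariateStack:
    """Named covariate layers sharing one GridSpec."""

    grid: GridSpec
    layers: dict[str, Raster] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, layer: Raster) -> None:
        if (layer.x_min, layer.y_min, layer.resolution,
                layer.values.shape) != (self.grid.x_min, self.grid.y_min,
                                        self.grid.cell_size,
                                        (self.grid.n_rows, self.grid.n_cols)):
            raise ValueError(f"layer {name!r} does not align with the stack grid")
        self.layers[name] = layer

    def values_at(self, xy: np.ndarray) -> np.ndarray:
        """Covariate matrix (n_points, n_layers) by nearest-cell lookup.

        Cell assignment uses the half-open convention [x0, x0 + cell).
        Raises on points outside the grid extent, listing the offenders.
        """
        xy = np.asarray(xy, dtype=float)
        g = self.grid
        cols = np.floor((xy[:, 0] - g.x_min) / g.cell_size).astype(int)
        rows = np.floor((g.y_max - xy[:, 1]) / g.cell_size).astype(int)
        rows[xy[:, 1] == g.y_min] = g.n_rows - 1
        bad = (rows < 0) | (rows >= g.n_rows) | (cols < 0) | (cols >= g.n_cols)
        if bad.any():
            raise ValueError(
                f"points outside grid extent at rows {np.flatnonzero(bad).tolist()}")
        return np.column_stack(
            [self.layers[name].values[rows, cols] for name in self.names])

    # ---- I/O: one .asc per layer plus a JSON index --------------------
    def write(self, directory: str | Path) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            layer.write_ascii(directory / f"{name}.asc")
        meta = {"cell_size": self.grid.cell_size, "crs": self.grid.crs,
                "layers": self.names}
        with open(directory / "stack.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, directory: str | Path) -> "CovariateStack":
        import json

        directory = Path(directory)
        with open(directory / "stack.json") as fh:
            meta = json.load(fh)
        layers = {name: Raster.read_ascii(directory / f"{name}.asc", crs=meta["crs"])
                  for name in meta["layers"]}
        first = next(iter(layers.values()))
        grid = GridSpec(first.x_min, first.y_min, first.n_rows, first.n_cols,
                        first.resolution, meta["crs"])
        stack = cls(grid)
        for name, layer in layers.items():
            stack.add(name, layer)
        return stack


def assemble_stack(grid: GridSpec, **layers: Raster) -> CovariateStack:
    """Bundle aligned layers into a stack; misaligned layers raise."""
    stack = CovariateStack(grid)
    for name, layer in layers.items():
        stack.add(name, layer)
    return stack


FINAL_MODEL_PRESET = ("density_ge60_5ac", "sumht_ge50_5ac", "sdht_ge50_5ac")


def final_model_stack(taos: TAOSet, grid: GridSpec) -> CovariateStack:
    """The final model's covariate trio on the analysis grid."""
    return assemble_stack(
        grid,
        density_ge60_5ac=tao_window_stat(taos, grid, "count_density", 60.0, 5.0),
        sumht_ge50_5ac=tao_window_stat(taos, grid, "sum", 50.0, 5.0),
        sdht_ge50_5ac=tao_window_stat(taos, grid, "sd", 50.0, 5.0),
    )
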