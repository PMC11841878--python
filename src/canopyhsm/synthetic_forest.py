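"""Synthetic forest landscapes for end-to-end testing of the habitat pipeline.

Real inputs to this kind of analysis — a LiDAR canopy surface over managed
timberland and survey-derived occupied-habitat polygons — are typically
proprietary.  This module generates landscapes with the same statistical
structure: a second-growth matrix (canopy mostly below 50 m) containing
old-growth patches that carry an extra population of very tall trees
(60 m and taller, up to roughly 25 stems/ha, heights approaching 110 m).
The patch polygons double as the "used" (occupied) habitat polygons, so
every downstream stage has ground truth.

Trees are placed by a homogeneous Poisson process; each tree renders into
the canopy surface as a paraboloid crown whose radius is proportional to
its height.  The ground is flat zero — the surface is canopy height above
ground, standing in for a canopy DSM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon, box

from .raster import Raster

HA = 10_000.0  # m^2 per hectare


@dataclass(frozen=True)
class HeightDistribution:
    """Distribution spec for tree heights (meters).

    families: "truncnorm" (mean, sd, low, high), "uniform" (low, high),
    "constant" (value).
    """

    family: str
    params: dict

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "truncnorm":
            a = (p["low"] - p["mean"]) / p["sd"]
            b = (p["high"] - p["mean"]) / p["sd"]
            return stats.truncnorm.rvs(
                a, b, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
            )
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "constant":
            return np.full(n, float(p["value"]))
        raise ValueError(f"unknown height distribution family {self.family!r}")

    @property
    def upper_bound(self) -> float:
        p = self.params
        if self.family == "truncnorm":
            return p["high"]
        if self.family == "uniform":
            return p["high"]
        return float(p["value"])


def default_matrix_heights() -> HeightDistribution:
    # second/third growth: closed canopy mostly 15-45 m
    return HeightDistribution("truncnorm", dict(mean=28.0, sd=9.0, low=2.0, high=50.0))


def default_tall_heights() -> HeightDistribution:
    # residual old growth: 60 m and taller, up to ~110 m
    return HeightDistribution("truncnorm", dict(mean=80.0, sd=12.0, low=60.0, high=110.0))


@dataclass(frozen=True)
class PatchSpec:
    """An old-growth patch: polygon plus its extra tall-tree population."""

    polygon: Polygon
    tall_tree_density: float = 25.0          # trees/ha of trees >= 60 m
    tall_height_dist: HeightDistribution = field(default_factory=default_tall_heights)


@dataclass(frozen=True)
class ForestScenario:
    """Everything needed to generate one reproducible synthetic landscape."""

    extent: tuple[float, float, float, float]       # x_min, y_min, x_max, y_max
    matrix_height_dist: HeightDistribution = field(default_factory=default_matrix_heights)
    matrix_stem_density: float = 150.0              # canopy-forming trees/ha
    patches: tuple[PatchSpec, ...] = ()
    crown_radius_coeff: float = 0.1                 # crown radius per m of height
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("scenario extent must have positive area")
        if self.matrix_stem_density < 0:
            raise ValueError("densities must be >= 0")
        ext = box(*self.extent)
        for p in self.patches:
            if p.tall_tree_density < 0:
                raise ValueError("densities must be >= 0")
            if p.tall_height_dist.upper_bound > 120.0:
                raise ValueError("tall height distribution must be supported on <= 120 m")
            if not ext.buffer(1e-6).contains(p.polygon):
                raise ValueError("patch polygons must lie inside the extent")

    @property
    def area_ha(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0) / HA


@dataclass
class StemMap:
    """Ground-truth tree list: columns x, y (m) and height (m)."""

    x: np.ndarray
    y: np.ndarray
    height: np.ndarray
    scenario_seed: int = 0

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "height_m": self.height})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0) -> "StemMap":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   df["height_m"].to_numpy(), scenario_seed=seed)


def _poisson_points_in_polygon(
    polygon: Polygon, density_per_ha: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson point process inside a polygon (rejection from bbox)."""
    area_ha = polygon.area / HA
    n = rng.poisson(density_per_ha * area_ha)
    if n == 0:
        return np.empty(0), np.empty(0)
    x0, y0, x1, y1 = polygon.bounds
    xs, ys = [], []
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cx = rng.uniform(x0, x1, m)
        cy = rng.uniform(y0, y1, m)
        import shapely

        inside = shapely.contains_xy(polygon, cx, cy)
        take = min(n - got, int(inside.sum()))
        xs.append(cx[inside][:take])
        ys.append(cy[inside][:take])
        got += take
    return np.concatenate(xs), np.concatenate(ys)


def generate_stem_map(scenario: ForestScenario) -> StemMap:
    """Place matrix and patch trees by independent Poisson processes.

    Matrix trees cover the whole extent (patches included — old growth sits
    on top of regrowth understory canopy); each patch adds its tall-tree
    population.  Same scenario (including seed) -> identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    ext_poly = box(*scenario.extent)
    xs, ys = _poisson_points_in_polygon(ext_poly, scenario.matrix_stem_density, rng)
    hs = scenario.matrix_height_dist.sample(xs.size, rng)
    all_x, all_y, all_h = [xs], [ys], [hs]
    for patch in scenario.patches:
        px, py = _poisson_points_in_polygon(patch.polygon, patch.tall_tree_density, rng)
        ph = patch.tall_height_dist.sample(px.size, rng)
        all_x.append(px)
        all_y.append(py)
        all_h.append(ph)
    return StemMap(
        np.concatenate(all_x), np.concatenate(all_y), np.concatenate(all_h),
        scenario_seed=scenario.seed,
    )


def render_dsm(
    stem_map: StemMap,
    extent: tuple[float, float, float, float],
    resolution: float = 1.0,
    crown_radius_coeff: float = 0.1,
    crs: str = "local-meters",
) -> Raster:
    """Rasterize a stem map into a canopy height surface.

    Each tree contributes a paraboloid crown: height h at the apex, falling
    to zero at radius ``crown_radius_coeff * h``.  A cell's value is the
    maximum over all contributing crowns (0 where none reach).  Evaluated
    at cell centers, so the apex cell reads the tree height minus at most
    the paraboloid drop across half a cell.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    x0, y0, x1, y1 = extent
    n_cols = int(np.ceil((x1 - x0) / resolution))
    n_rows = int(np.ceil((y1 - y0) / resolution))
    vals = np.zeros((n_rows, n_cols))
    y_max = y0 + n_rows * resolution
    for tx, ty, h in zip(stem_map.x, stem_map.y, stem_map.height):
        radius = crown_radius_coeff * h
        if radius <= 0:
            continue
        c_lo = max(int((tx - radius - x0) / resolution), 0)
        c_hi = min(int((tx + radius - x0) / resolution) + 1, n_cols)
        r_lo = max(int((y_max - ty - radius) / resolution), 0)
        r_hi = min(int((y_max - ty + radius) / resolution) + 1, n_rows)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        cx = x0 + (np.arange(c_lo, c_hi) + 0.5) * resolution
        cy = y_max - (np.arange(r_lo, r_hi) + 0.5) * resolution
        dx = cx[None, :] - tx
        dy = cy[:, None] - ty
        d2 = dx * dx + dy * dy
        crown = h * (1.0 - d2 / (radius * radius))
        np.maximum(vals[r_lo:r_hi, c_lo:c_hi], np.clip(crown, 0.0, None),
                   out=vals[r_lo:r_hi, c_lo:c_hi])
    return Raster(vals, x0, y0, resolution, crs)


def used_polygons_from_scenario(scenario: ForestScenario) -> list[Polygon]:
    """The old-growth patch polygons, labeled as used (occupied) habitat."""
    return [p.polygon for p in scenario.patches]


# ---- vector I/O -------------------------------------------------------

def write_polygons_geojson(polygons: list[Polygon], path: str | Path) -> None:
    import json

    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
        for i, p in enumerate(polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons_geojson(path: str | Path) -> list[Polygon]:
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    return [shape(f["geometry"]) for f in gj["features"]]


def demo_scenario(seed: int = 0, size_m: float = 2500.0, n_patches: int = 4,
                  patch_size_range: tuple[float, float] = (300.0, 450.0),
                  ) -> ForestScenario:
    """A small landscape with rectangular old-growth patches, for demos/tests."""
    rng = np.random.default_rng(seed)
    patches = []
    placed: list[Polygon] = []
    margin = 120.0
    hi = max(min(patch_size_range[1], size_m - 2 * margin - 10.0), 50.0)
    lo = min(patch_size_range[0], hi)
    for _ in range(200):
        if len(patches) >= n_patches:
            break
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        px = rng.uniform(margin, size_m - margin - w)
        py = rng.uniform(margin, size_m - margin - h)
        poly = box(px, py, px + w, py + h)
        if all(poly.distance(q) > 150.0 for q in placed):
            patches.append(PatchSpec(polygon=poly))
            placed.append(poly)
    return ForestScenario(
        extent=(0.0, 0.0, size_m, size_m),
        patches=tuple(patches),
        seed=seed,
    )
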