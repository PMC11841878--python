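"""Habitat patch delineation: class raster + tall trees -> management polygons.

Cells of "low" or better habitat are polygonized (4-connectivity) and
buffered outward by the 5-acre window radius (80.25 m), because trees that
far away contributed to the predictions inside the patch.  All TAOs of
50 m and taller inside a dissolved buffer region are wrapped in a concave
hull (concaveman-style, concavity 0.8), whose perimeter is then smoothed
by a 60-m outward / 55-m inward buffer — a morphological closing plus a
5-m dilation that removes narrow bays and always contains the hull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, box
from shapely.ops import unary_union

from .covariates import ACRE_M2, circle_radius_for_area
from .raster import Raster
from .tao_detect import TAOSet

HA = 10_000.0
DEFAULT_BUFFER = 80.25          # m; radius of the 5-acre moving window
DEFAULT_TAO_MIN_HEIGHT = 50.0   # m
DEFAULT_CONCAVITY = 0.8
DEFAULT_SMOOTH_OUT = 60.0       # m
DEFAULT_SMOOTH_IN = 55.0        # m


def habitat_mask(class_raster: Raster, min_class: int) -> list[Polygon]:
    """Dissolved polygons of cells with class code >= min_class.

    Components are 4-connected (diagonal cells form separate patches);
    each polygon is a union of cell squares with counterclockwise
    exteriors.
    """
    qual = class_raster.values >= min_class
    if not qual.any():
        return []
    labels, n_lab = ndimage.label(qual)  # default structure = 4-connectivity
    res = class_raster.resolution
    y_max = class_raster.y_max
    x_min = class_raster.x_min
    polys = []
    idx = ndimage.value_indices(labels, ignore_value=0)
    for lab in sorted(idx):
        rr, cc = idx[lab]
        cells = [
            box(x_min + c * res, y_max - (r + 1) * res,
                x_min + (c + 1) * res, y_max - r * res)
            for r, c in zip(rr, cc)
        ]
        merged = unary_union(cells)
        merged = shapely.normalize(merged)
        if isinstance(merged, MultiPolygon):  # corner-touching cells
            polys.extend(merged.geoms)
        else:
            polys.append(merged)
    return polys


def buffer_and_collect(
    mask_polygons: list[Polygon],
    taos: TAOSet,
    buffer: float = DEFAULT_BUFFER,
    tao_min_height: float = DEFAULT_TAO_MIN_HEIGHT,
) -> list[np.ndarray]:
    """Group qualifying TAOs by dissolved buffered habitat region.

    Each mask polygon grows by ``buffer``; overlapping buffers dissolve
    into one region, and each region collects the (x, y) of TAOs with
    height >= ``tao_min_height`` that fall inside it.  Returns one
    (n_i, 2) coordinate array per region (empty regions included).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    if not mask_polygons:
        return []
    dissolved = unary_union([p.buffer(buffer) for p in mask_polygons])
    regions = (list(dissolved.geoms) if isinstance(dissolved, MultiPolygon)
               else [dissolved])
    regions.sort(key=lambda g: (-g.area, g.centroid.x, g.centroid.y))
    tall = taos.height >= tao_min_height
    xs, ys = taos.x[tall], taos.y[tall]
    groups = []
    for region in regions:
        inside = shapely.contains_xy(region, xs, ys) | shapely.intersects(
            region.boundary, shapely.points(xs, ys))
        groups.append(np.column_stack([xs[inside], ys[inside]]))
    return groups


# ------------------------------------------------------------ concave hull
def _seg_dist2(px, py, ax, ay, bx, by) -> float:
    """Squared distance from point p to segment ab."""
    abx, aby = bx - ax, by - ay
    apx, apy = px - ax, py - ay
    denom = abx * abx + aby * aby
    t = 0.0 if denom == 0 else max(0.0, min(1.0, (apx * abx + apy * aby) / denom))
    dx, dy = apx - t * abx, apy - t * aby
    return dx * dx + dy * dy


def concave_hull(
    points: np.ndarray,
    concavity: float = DEFAULT_CONCAVITY,
    length_threshold: float = 0.0,
) -> Polygon:
    """Concave hull by edge digging from the convex hull.

    Starting from the convex hull, each edge longer than
    ``length_threshold`` may be replaced by two edges through the interior
    point nearest to it, provided (a) the point's distance to the edge is
    within edge_length / concavity (relative concavity bound — larger
    concavity digs less, converging to the convex hull), (b) the new edges
    do not cross the current hull boundary, and (c) no other point lies
    inside the triangle being carved, which guarantees every input point
    stays inside the hull.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points")
    mp = shapely.multipoints(pts)
    convex = mp.convex_hull
    if not isinstance(convex, Polygon):
        raise ValueError("points are collinear")
    if concavity <= 0:
        raise ValueError("concavity must be > 0")

    ring = list(np.asarray(convex.exterior.coords)[:-1])
    hull_set = {tuple(p) for p in ring}
    interior = [tuple(p) for p in pts if tuple(p) not in hull_set]
    sq_concavity = concavity * concavity
    sq_len_threshold = length_threshold * length_threshold

    queue = list(range(len(ring)))
    while queue and interior:
        # process the currently longest queued edge first
        queue.sort(key=lambda i: -(
            (ring[(i + 1) % len(ring)][0] - ring[i][0]) ** 2
            + (ring[(i + 1) % len(ring)][1] - ring[i][1]) ** 2))
        i = queue.pop(0)
        n = len(ring)
        a, b = ring[i % n], ring[(i + 1) % n]
        sq_len = (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2
        if sq_len <= sq_len_threshold:
            continue
        max_sq_dist = sq_len / sq_concavity
        # nearest interior point to this edge
        best_j, best_d2 = -1, np.inf
        for j, p in enumerate(interior):
            d2 = _seg_dist2(p[0], p[1], a[0], a[1], b[0], b[1])
            if d2 < best_d2:
                best_j, best_d2 = j, d2
        if best_j < 0 or best_d2 > max_sq_dist:
            continue
        p = interior[best_j]
        # (b) new edges must not cross the existing boundary
        boundary = LineString(ring + [ring[0]])
        e1, e2 = LineString([a, p]), LineString([p, b])
        crosses = False
        for e in (e1, e2):
            inter = e.intersection(boundary)
            # touching at a and b is fine; anything more is a crossing
            if inter.length > 1e-9 or (
                    not inter.is_empty
                    and any(not (Point(a).equals_exact(g, 1e-9)
                                 or Point(b).equals_exact(g, 1e-9))
                            for g in getattr(inter, "geoms", [inter]))):
                crosses = True
                break
        if crosses:
            continue
        # (c) empty-triangle guard: digging must not orphan another point
        tri = Polygon([a, b, p])
        if tri.area > 0 and any(
                k != best_j and tri.contains(Point(q)) for k, q in enumerate(interior)):
            continue
        # dig: replace edge (a, b) with (a, p), (p, b)
        pos = (i % n) + 1
        ring.insert(pos, p)
        interior.pop(best_j)
        queue = [q if q < pos else q + 1 for q in queue]
        queue.extend([pos - 1, pos])
    hull = Polygon(ring)
    if not hull.is_valid:
        hull = hull.buffer(0)
    return hull


def smooth_perimeter(
    polygon: Polygon,
    out: float = DEFAULT_SMOOTH_OUT,
    inward: float = DEFAULT_SMOOTH_IN,
) -> Polygon:
    """Outward buffer then inward buffer (default 60 m out, 55 m in).

    Equivalent to a morphological closing at the inward radius followed
    by a dilation at (out - inward); the result always contains the
    input, and bays narrower than twice the closing radius are filled.
    """
    if polygon.is_empty:
        return polygon
    return polygon.buffer(out, quad_segs=16).buffer(-inward, quad_segs=16)


@dataclass
class Patch:
    polygon: Polygon
    tao_xy: np.ndarray
    area_ha: float
    area_acres: float
    mean_hsi: float
    median_hsi: float
    max_hsi: float
    class_area_ha: dict[int, float]
    status: str                     # "used" | "available"


@dataclass
class PatchSet:
    patches: list[Patch]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patches)

    def to_geojson(self, path: str | Path) -> None:
        import json

        from shapely.geometry import mapping

        feats = []
        for p in self.patches:
            props = {"area_ha": p.area_ha, "area_acres": p.area_acres,
                     "mean_hsi": p.mean_hsi, "median_hsi": p.median_hsi,
                     "max_hsi": p.max_hsi, "status": p.status}
            props.update({f"class_ha_{k}": v for k, v in p.class_area_ha.items()})
            feats.append({"type": "Feature", "properties": props,
                          "geometry": mapping(p.polygon)})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats,
                       "provenance": self.provenance}, fh)


def delineate_patches(
    class_raster: Raster,
    taos: TAOSet,
    min_class: int,
    buffer: float = DEFAULT_BUFFER,
    tao_min_height: float = DEFAULT_TAO_MIN_HEIGHT,
    concavity: float = DEFAULT_CONCAVITY,
    smooth_out: float = DEFAULT_SMOOTH_OUT,
    smooth_in: float = DEFAULT_SMOOTH_IN,
) -> tuple[list[Polygon], list[np.ndarray]]:
    """Full delineation chain: mask -> buffer -> collect -> hull -> smooth.

    Returns the smoothed patch polygons and, aligned with them, the TAO
    coordinate groups they were built from.  Groups with fewer than 3
    tall TAOs cannot support a hull and are dropped with a warning.
    """
    mask = habitat_mask(class_raster, min_class)
    groups = buffer_and_collect(mask, taos, buffer, tao_min_height)
    polys, kept_groups = [], []
    for grp in groups:
        if np.unique(grp, axis=0).shape[0] < 3:
            warnings.warn(f"dropping degenerate patch group with {grp.shape[0]} "
                          "tall TAOs (hull needs 3)")
            continue
        try:
            hull = concave_hull(grp, concavity=concavity)
        except ValueError:
            warnings.warn("dropping collinear patch group")
            continue
        polys.append(smooth_perimeter(hull, smooth_out, smooth_in))
        kept_groups.append(grp)
    return polys, kept_groups


def summarize_patches(
    patch_polygons: list[Polygon],
    tao_groups: list[np.ndarray],
    hsi_raster: Raster,
    class_raster: Raster,
    used_polygons: list[Polygon],
    provenance: dict | None = None,
) -> PatchSet:
    """Per-patch area, HSI summary, class-area breakdown and used status.

    Cell membership is by cell-center-in-polygon; a patch whose polygon
    covers no cell centers raises.  Status is "used" when the patch
    intersects any used polygon.
    """
    X, Y = hsi_raster.cell_centers()
    xs, ys = X.ravel(), Y.ravel()
    hsi = hsi_raster.values.ravel()
    cls = class_raster.values.ravel()
    cell_area_ha = hsi_raster.resolution**2 / HA
    used_union = unary_union(used_polygons) if used_polygons else None
    patches = []
    for poly, grp in zip(patch_polygons, tao_groups):
        inside = shapely.contains_xy(poly, xs, ys)
        if not inside.any():
            raise ValueError("patch polygon covers no raster cells")
        vals = hsi[inside]
        classes = cls[inside]
        class_ha = {int(c): float((classes == c).sum() * cell_area_ha)
                    for c in np.unique(classes)}
        status = ("used" if used_union is not None
                  and poly.intersects(used_union) else "available")
        patches.append(Patch(
            polygon=poly, tao_xy=grp,
            area_ha=poly.area / HA, area_acres=poly.area / ACRE_M2,
            mean_hsi=float(vals.mean()), median_hsi=float(np.median(vals)),
            max_hsi=float(vals.max()), class_area_ha=class_ha, status=status))
    patches.sort(key=lambda p: (-p.area_ha, p.polygon.centroid.x,
                                p.polygon.centroid.y))
    return PatchSet(patches, provenance or {})
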