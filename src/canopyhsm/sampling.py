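"""Balanced acceptance sampling (BAS) and used/available labeling.

BAS draws spatially balanced points from the random-start 2-D Halton
sequence (bases 2 and 3): points are generated in sequence order, scaled
to the region's bounding box, and accepted when they fall inside the
region, until the requested count is reached.  Points inside an occupied
("used") polygon and at least an exclusion distance (default 20 m) from
its boundary are labeled used; *every* accepted point, used or not,
belongs to the available pool — the two-sample used/available design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

HA = 10_000.0


def radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    """Van der Corput radical inverse of integer indices in the given base."""
    indices = np.asarray(indices, dtype=np.int64)
    out = np.zeros(indices.shape, dtype=float)
    f = 1.0 / base
    idx = indices.copy()
    while np.any(idx > 0):
        out += f * (idx % base)
        idx //= base
        f /= base
    return out


def halton_2d(start: int, n: int, offsets: tuple[int, int] = (0, 0)) -> np.ndarray:
    """n points of the 2-D Halton sequence (bases 2, 3) with index offsets."""
    idx = np.arange(start, start + n, dtype=np.int64)
    return np.column_stack([
        radical_inverse(idx + offsets[0], 2),
        radical_inverse(idx + offsets[1], 3),
    ])


MAX_OFFSET = 10_000_000  # random-start offsets drawn uniformly from [0, 1e7)


def bas_points(
    region: Polygon,
    n: int,
    seed: int | None = 0,
    offsets: tuple[int, int] | None = None,
) -> np.ndarray:
    """Draw n BAS points inside ``region``; sequence order retained.

    The random start is a pair of independent uniform integer Halton index
    offsets (one per base) derived from ``seed``; pass ``offsets=(0, 0)``
    for the plain Halton sequence.
    """
    if region.is_empty or region.area <= 0:
        raise ValueError("region must have positive area")
    if n < 1:
        raise ValueError("n must be >= 1")
    if offsets is None:
        rng = np.random.default_rng(seed)
        offsets = tuple(int(v) for v in rng.integers(0, MAX_OFFSET, size=2))
    x0, y0, x1, y1 = region.bounds
    accepted: list[np.ndarray] = []
    got = 0
    start = 1  # index 0 maps to the bbox corner; start at 1 as is conventional
    # expected acceptance rate = region area / bbox area
    rate = max(region.area / ((x1 - x0) * (y1 - y0)), 1e-6)
    while got < n:
        m = int(np.ceil((n - got) / rate * 1.2)) + 16
        u = halton_2d(start, m, offsets)
        pts = np.column_stack([x0 + u[:, 0] * (x1 - x0), y0 + u[:, 1] * (y1 - y0)])
        inside = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
        sel = pts[inside]
        take = min(n - got, sel.shape[0])
        accepted.append(sel[:take])
        got += take
        start += m
    return np.concatenate(accepted, axis=0)


def target_n_for_density(region_area_ha: float, ha_per_point: float) -> int:
    """Point count for an average density of one point per ``ha_per_point`` ha."""
    if region_area_ha <= 0 or ha_per_point <= 0:
        raise ValueError("region area and ha_per_point must be > 0")
    return int(round(region_area_ha / ha_per_point))


@dataclass
class LabeledSample:
    """BAS points with used/available labels and (optionally) covariates."""

    points: np.ndarray                       # (n, 2)
    used: np.ndarray                         # boolean mask
    covariates: pd.DataFrame | None = None   # one column per covariate layer
    design: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def n_used(self) -> int:
        return int(self.used.sum())

    def used_points(self) -> np.ndarray:
        return self.points[self.used]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x": self.points[:, 0], "y": self.points[:, 1],
                           "label": np.where(self.used, "used", "available")})
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledSample":
        df = pd.read_csv(path)
        pts = df[["x", "y"]].to_numpy()
        used = (df["label"] == "used").to_numpy()
        cov_cols = [c for c in df.columns if c not in ("x", "y", "label")]
        cov = df[cov_cols] if cov_cols else None
        return cls(pts, used, cov)


def label_samples(
    points: np.ndarray,
    used_polygons: list[Polygon],
    exclusion: float = 20.0,
) -> LabeledSample:
    """Label BAS points used/available with the inner-boundary exclusion.

    A point is used iff it lies inside a used polygon *and* its distance
    to that polygon's boundary is >= ``exclusion`` (inclusive) — the
    20-m rule that removes moving-window edge effects near patch
    boundaries.  All points remain in the available pool.
    """
    if exclusion < 0:
        raise ValueError("exclusion must be >= 0")
    points = np.asarray(points, dtype=float)
    used = np.zeros(points.shape[0], dtype=bool)
    for poly in used_polygons:
        if not poly.is_valid:
            raise ValueError("invalid used polygon")
        # inward negative buffer: the region >= exclusion from the boundary
        core = poly.buffer(-exclusion) if exclusion > 0 else poly
        if core.is_empty:
            continue
        inside = shapely.contains_xy(core, points[:, 0], points[:, 1])
        if exclusion > 0:
            # buffer(-d) is open at distance exactly d; include the == case
            boundary_dist = shapely.distance(
                shapely.boundary(poly),
                shapely.points(points[:, 0], points[:, 1]))
            in_poly = shapely.contains_xy(poly, points[:, 0], points[:, 1])
            inside = inside | (in_poly & np.isclose(boundary_dist, exclusion))
        used |= inside
    return LabeledSample(points, used,
                         design={"exclusion_m": exclusion,
                                 "n_used": int(used.sum()),
                                 "n_available": int(points.shape[0])})


def extract_design(sample: LabeledSample, stack) -> tuple[np.ndarray, np.ndarray]:
    """(used matrix, available matrix) of covariate vectors, in sample order.

    Values come from the covariate stack by nearest-cell lookup.  The
    available matrix contains *all* points (used points included), per the
    two-sample design.
    """
    values = stack.values_at(sample.points)
    sample.covariates = pd.DataFrame(values, columns=stack.names)
    return values[sample.used], values
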