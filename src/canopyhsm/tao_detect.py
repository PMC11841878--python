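"""Individual tree detection: tree-approximate objects (TAOs) from a canopy surface.

A TAO is the (x, y, height) of a putative tree top, found as a local
maximum of the canopy height raster within a circular window.  Plateaus of
equal value are collapsed to a single TAO at the plateau's centroid cell
(ties broken by row-major scan order), and neighborhoods are clipped at
the raster edge, so edge cells can be maxima of their partial window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster


@dataclass
class TAOSet:
    """Detected tree tops. Coordinates are cell centers; heights are cell values."""

    x: np.ndarray
    y: np.ndarray
    height: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.height = np.asarray(self.height, dtype=float)

    def __len__(self) -> int:
        return self.x.size

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "height_m": self.height})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TAOSet":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["height_m"].to_numpy())

    def to_geojson(self, path: str | Path) -> None:
        import json

        feats = [
            {
                "type": "Feature",
                "properties": {"height_m": float(h)},
                "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            }
            for x, y, h in zip(self.x, self.y, self.height)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _circular_footprint(window_radius: float, resolution: float) -> np.ndarray:
    """Boolean mask of cells whose centers lie within window_radius of the center cell."""
    n = int(np.floor(window_radius / resolution))
    offsets = np.arange(-n, n + 1) * resolution
    d2 = offsets[:, None] ** 2 + offsets[None, :] ** 2
    return d2 <= window_radius**2 + 1e-9


def extract_taos(
    dsm: Raster, window_radius: float = 2.0, min_height: float = 0.0
) -> TAOSet:
    """Detect TAOs as circular-window local maxima of the canopy surface.

    A cell is a candidate iff its value is positive, >= ``min_height`` and
    >= every cell within ``window_radius`` of its center.  Jointly-maximal
    plateaus (connected candidates of equal value) emit one TAO at the
    candidate cell closest to the plateau centroid, first in row-major
    order on ties.
    """
    if window_radius < dsm.resolution:
        raise ValueError("window_radius must be >= raster resolution")
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    vals = dsm.values
    if vals.size == 0:
        return TAOSet(np.empty(0), np.empty(0), np.empty(0))
    footprint = _circular_footprint(window_radius, dsm.resolution)
    local_max = ndimage.maximum_filter(
        vals, footprint=footprint, mode="constant", cval=-np.inf
    )
    candidate = (vals >= local_max) & (vals >= min_height) & (vals > 0)

    # collapse plateaus: connected candidate cells sharing one value
    labels, n_lab = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    rows, cols, heights = [], [], []
    if n_lab:
        idx = ndimage.value_indices(labels, ignore_value=0)
        for lab in sorted(idx):
            rr, cc = idx[lab]
            if rr.size == 1:
                r, c = int(rr[0]), int(cc[0])
            else:
                cr, ccen = rr.mean(), cc.mean()
                d2 = (rr - cr) ** 2 + (cc - ccen) ** 2
                # ties -> row-major order (rr, cc already row-major sorted)
                k = int(np.argmin(d2))
                r, c = int(rr[k]), int(cc[k])
            rows.append(r)
            cols.append(c)
            heights.append(vals[r, c])
    rows_a = np.asarray(rows, dtype=int)
    cols_a = np.asarray(cols, dtype=int)
    xs = dsm.x_min + (cols_a + 0.5) * dsm.resolution
    ys = dsm.y_max - (rows_a + 0.5) * dsm.resolution
    return TAOSet(
        xs, ys, np.asarray(heights, dtype=float),
        source={"window_radius": window_radius, "min_height": min_height,
                "resolution": dsm.resolution},
    )


def filter_taos(taos: TAOSet, min_height: float) -> TAOSet:
    """Subset of TAOs with height >= min_height (boundary inclusive); order kept."""
    keep = taos.height >= min_height
    return TAOSet(taos.x[keep], taos.y[keep], taos.height[keep],
                  source=dict(taos.source))


def match_to_stems(
    taos: TAOSet, stem_x: np.ndarray, stem_y: np.ndarray,
    max_distance: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbor assignment of detected TAOs to planted stems.

    Returns (tao_index, stem_index) pairs of mutual matches within
    ``max_distance``; each stem and each TAO is used at most once.  Serves
    as the recall/precision oracle against ground-truth stem maps.
    """
    from scipy.spatial import cKDTree

    if len(taos) == 0 or stem_x.size == 0:
        return np.empty(0, int), np.empty(0, int)
    tree = cKDTree(np.column_stack([stem_x, stem_y]))
    dists, nearest = tree.query(taos.coords())
    order = np.argsort(dists)
    used_stems: set[int] = set()
    t_idx, s_idx = [], []
    for ti in order:
        if dists[ti] > max_distance:
            break
        si = int(nearest[ti])
        if si in used_stems:
            continue
        used_stems.add(si)
        t_idx.append(int(ti))
        s_idx.append(si)
    return np.asarray(t_idx, int), np.asarray(s_idx, int)
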