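"""Habitat classification from the continuous P/E (predicted/expected) curve.

For overlapping HSI bins (width 0.02, centers from 0.02 upward in steps
of 0.002) the P/E ratio compares the proportion of used predictions in
the bin to the proportion of available predictions: P/E > 1 marks
selection.  The curve is smoothed, the first break is forced at the
highest HSI whose P/E is still below 1 (the unsuitable boundary), and
interior breakpoints are found by exhaustive direct search for the
best-fitting continuous piecewise-linear curve (OLS).  Breakpoints map
HSI rasters into ordered habitat classes (default labels unsuitable /
marginal / low / medium / high).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import Raster

DEFAULT_LABELS = ("unsuitable", "marginal", "low", "medium", "high")


@dataclass
class PECurve:
    centers: np.ndarray             # bin centers, strictly increasing
    half_width: float
    raw: np.ndarray                 # raw P/E per bin (nan where undefined)
    n_used: np.ndarray
    n_available: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.n_available > 0

    @property
    def values(self) -> np.ndarray:
        """Smoothed P/E where available, raw otherwise."""
        return self.raw if self.smoothed is None else self.smoothed

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "center": self.centers,
            "raw_pe": self.raw,
            "smoothed_pe": self.values,
            "n_used": self.n_used,
            "n_available": self.n_available,
            "defined": self.defined,
        }).to_csv(path, index=False)


def pe_curve(
    used_hsi: np.ndarray,
    available_hsi: np.ndarray,
    width: float = 0.02,
    step: float = 0.002,
    start: float = 0.02,
) -> PECurve:
    """Raw P/E ratios over overlapping HSI bins.

    Per bin b: P = share of used predictions in b, E = share of available
    predictions in b, P/E = P / E; bins with no available mass are flagged
    undefined (NaN) and excluded from fitting.
    """
    used_hsi = np.asarray(used_hsi, dtype=float)
    available_hsi = np.asarray(available_hsi, dtype=float)
    if used_hsi.size == 0 or available_hsi.size == 0:
        raise ValueError("both HSI samples must be nonempty")
    if width <= step:
        raise ValueError("bin width must exceed the step")
    if np.ptp(available_hsi) == 0:
        raise ValueError("constant predictions produce a degenerate curve")
    top = max(available_hsi.max(), used_hsi.max())
    centers = np.arange(start, top + step / 2, step)
    half = width / 2.0
    lo = centers[:, None] - half
    hi = centers[:, None] + half
    n_u = ((used_hsi[None, :] >= lo) & (used_hsi[None, :] <= hi)).sum(axis=1)
    n_a = ((available_hsi[None, :] >= lo) & (available_hsi[None, :] <= hi)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (n_u / used_hsi.size) / (n_a / available_hsi.size)
    ratio[n_a == 0] = np.nan
    return PECurve(centers, half, ratio, n_u, n_a)


def smooth_pe(curve: PECurve, span: float = 0.2) -> PECurve:
    """Local-linear running smoother over the defined bins.

    Each defined bin is replaced by the value at its center of an OLS line
    fitted to the ``span`` fraction of defined bins nearest to it; a
    noiseless line is reproduced exactly.  Undefined bins stay NaN.
    """
    mask = curve.defined
    if mask.sum() < 10:
        raise ValueError("need at least 10 defined bins to smooth")
    x = curve.centers[mask]
    y = curve.raw[mask]
    m = x.size
    k = max(int(round(span * m)), 3)
    sm = np.full(curve.centers.size, np.nan)
    out = np.empty(m)
    half = k // 2
    for i in range(m):
        lo = max(0, min(i - half, m - k))
        window = slice(lo, lo + k)
        xs, ys = x[window], y[window]
        xb, yb = xs.mean(), ys.mean()
        sxx = ((xs - xb) ** 2).sum()
        slope = 0.0 if sxx == 0 else ((xs - xb) * (ys - yb)).sum() / sxx
        out[i] = yb + slope * (x[i] - xb)
    sm[mask] = out
    return PECurve(curve.centers, curve.half_width, curve.raw,
                   curve.n_used, curve.n_available, smoothed=sm)


def forced_unsuitable_break(curve: PECurve) -> float:
    """Largest bin center whose (smoothed) P/E is below 1.0.

    HSI values up to this break contain fewer used points than expected
    by chance and form the unsuitable class.  Degenerate curves (entirely
    above or below 1) warn and return the first or last center.
    """
    vals = curve.values
    mask = curve.defined & np.isfinite(vals)
    below = mask & (vals < 1.0)
    if not below.any():
        warnings.warn("P/E ratio never drops below 1; "
                      "forcing break at the first bin center")
        return float(curve.centers[mask][0] if mask.any() else curve.centers[0])
    if not (mask & (vals >= 1.0)).any():
        warnings.warn("P/E ratio never reaches 1; habitat is all unsuitable")
    return float(curve.centers[below].max())


@dataclass
class BreakpointFit:
    forced_break: float
    breakpoints: tuple[float, ...]   # interior breakpoints, sorted
    coef: np.ndarray                 # [intercept, slope, hinge slopes...]
    sse: float
    candidates: np.ndarray           # the searched breakpoint grid

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cols = [np.ones_like(x), x]
        for b in self.breakpoints:
            cols.append(np.clip(x - b, 0, None))
        return np.column_stack(cols) @ self.coef


def _piecewise_design(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.clip(x - b, 0, None))
    return np.column_stack(cols)


def fit_breakpoints(
    curve: PECurve,
    k: int,
    forced_break: float | None = None,
    max_candidates: int = 40,
) -> BreakpointFit:
    """Best continuous piecewise-linear fit to the (smoothed) P/E curve.

    Exhaustive direct search over all C(m, k) combinations of candidate
    breakpoints (bin centers above the forced break; evenly thinned to at
    most ``max_candidates`` when the grid is large), minimizing the OLS
    SSE of a hinge-basis piecewise-linear model.  Ties go to the
    lexicographically smallest breakpoint set.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if forced_break is None:
        forced_break = forced_unsuitable_break(curve)
    vals = curve.values
    mask = curve.defined & np.isfinite(vals) & (curve.centers > forced_break)
    x = curve.centers[mask]
    y = vals[mask]
    if x.size < k + 2:
        raise ValueError("too few defined bins above the forced break")
    interior = x[1:-1]
    if interior.size > max_candidates:
        sel = np.unique(np.linspace(0, interior.size - 1, max_candidates).round()
                        .astype(int))
        candidates = interior[sel]
    else:
        candidates = interior
    if k > candidates.size:
        raise ValueError(f"k={k} exceeds the {candidates.size} candidate centers")

    best: tuple[float, tuple[float, ...], np.ndarray] | None = None
    for combo in itertools.combinations(candidates, k):
        design = _piecewise_design(x, combo)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, combo, coef)
    assert best is not None
    sse, combo, coef = best
    return BreakpointFit(forced_break, combo, coef, sse, candidates)


def fit_breakpoints_bruteforce(
    x: np.ndarray, y: np.ndarray, k: int, candidates: np.ndarray
) -> tuple[tuple[float, ...], float]:
    """Independent exhaustive search (per-combination normal equations);
    oracle for fit_breakpoints on small curves."""
    best_sse, best_combo = np.inf, ()
    for combo in itertools.combinations(np.asarray(candidates, dtype=float), k):
        design = _piecewise_design(np.asarray(x, dtype=float), combo)
        coef = np.linalg.pinv(design) @ y
        sse = float(((y - design @ coef) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best_combo = sse, combo
    return best_combo, best_sse


@dataclass
class HabitatClasses:
    boundaries: tuple[float, ...]    # strictly increasing, includes top
    labels: tuple[str, ...]          # len(boundaries) == len(labels)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries):
            raise ValueError("need one label per class "
                             "(boundaries include the top of the last class)")
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def classify(self, hsi: np.ndarray) -> np.ndarray:
        """Integer class codes; intervals left-closed [b_i, b_{i+1}),
        final class closed above, values above the top clamp with warning."""
        hsi = np.asarray(hsi, dtype=float)
        if (hsi < 0).any():
            raise ValueError("negative HSI values")
        # edges: [0, b_0, ..., b_{n-2}]; code i covers [edge_i, edge_{i+1})
        edges = self.boundaries[:-1]
        codes = np.searchsorted(edges, hsi, side="right")
        top = self.boundaries[-1]
        if (hsi > top).any():
            warnings.warn("HSI values above the top class boundary; clamped")
        return np.minimum(codes, self.n_classes - 1)

    def to_json(self, path: str | Path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({"labels": list(self.labels),
                       "boundaries": list(self.boundaries)}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "HabitatClasses":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["boundaries"]), tuple(d["labels"]))


def build_classes(
    forced_break: float,
    fit: BreakpointFit | tuple[float, ...],
    max_hsi: float,
    merges: tuple[float, ...] = (),
    labels: tuple[str, ...] | None = None,
) -> HabitatClasses:
    """Classes from the forced break plus retained interior breakpoints.

    ``merges`` is the explicit, caller-supplied list of breakpoints to
    drop, combining their adjacent classes (the manual curation step —
    never automated).  Boundaries become (forced, retained..., max_hsi)
    with the first class starting at 0.
    """
    breaks = fit.breakpoints if isinstance(fit, BreakpointFit) else tuple(fit)
    for m in merges:
        if not any(np.isclose(m, b) for b in breaks):
            raise ValueError(f"merge {m} does not match a fitted breakpoint")
    kept = tuple(b for b in breaks if not any(np.isclose(b, m) for m in merges))
    boundaries = (forced_break, *kept, max_hsi)
    if labels is None:
        if len(boundaries) == len(DEFAULT_LABELS):
            labels = DEFAULT_LABELS
        else:
            labels = ("unsuitable",) + tuple(
                f"class_{i}" for i in range(1, len(boundaries)))
    return HabitatClasses(boundaries, labels)


def classify_grid(hsi_raster: Raster, classes: HabitatClasses) -> Raster:
    """Map an HSI raster to integer class codes (0 = lowest class)."""
    return hsi_raster.copy_with(
        classes.classify(hsi_raster.values).astype(float))
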