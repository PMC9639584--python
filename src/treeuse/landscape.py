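"""Class-level landscape aggregation metrics inside circular buffers.

Implements the four aggregation metrics used to characterize the treed
habitat surrounding each sampled tree, on a binary woody/open raster:

* **AI** (aggregation index): observed rook like-adjacencies of the focal
  class as a percentage of the maximum achievable for its area.
* **COHESION** (patch cohesion index): physical connectedness of the focal
  class, from per-patch perimeters and areas, normalized by window size.
* **CLUMPY** (clumpiness index): departure of the like-adjacency
  proportion from the spatially random expectation.
* **PAFRAC** (perimeter-area fractal dimension): shape complexity from the
  slope of the log-log perimeter-area scaling across patches.

Patches are 8-connected; adjacency counts for AI and CLUMPY use rook
(4-neighbour) cell edges, the convention of the standard class-metric
software.  Edges against nodata or the window boundary count toward patch
perimeter but are excluded from adjacency totals, so the like-adjacency
proportion remains a proportion of observed adjacencies.  Degenerate
windows yield NaN (never a silent zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .raster import GridRaster

__all__ = [
    "CircularWindow",
    "circular_window",
    "patch_components",
    "aggregation_index",
    "cohesion_index",
    "clumpiness",
    "pafrac",
    "connectivity_table",
]


@dataclass
class CircularWindow:
    """A circular neighborhood clipped from a raster.

    ``raster`` is the bounding-box crop with cells outside the disc set to
    NaN; ``z`` is the number of retained (non-nodata) cells; ``partial`` is
    True when the disc extends past the source raster's extent, i.e. the
    buffer is not fully covered by data.
    """

    raster: GridRaster
    z: int
    partial: bool


def circular_window(raster: GridRaster, center: tuple[float, float],
                    radius: float = 50.0) -> CircularWindow:
    """Cells whose centers lie within ``radius`` of ``center``.

    Cells outside the disc (or outside the raster) become nodata.  Raises
    if the center itself lies outside the raster extent or radius <= 0.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    cx, cy = center
    if not raster.contains(cx, cy):
        raise ValueError(f"center {center} outside raster extent")
    xmin, ymin, xmax, ymax = raster.extent
    partial = (cx - radius < xmin or cx + radius > xmax
               or cy - radius < ymin or cy + radius > ymax)
    xs, ys = raster.cell_centers()
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
    rows, cols = np.nonzero(inside)
    if rows.size == 0:
        # radius smaller than half a cell: keep the center's own cell
        r, c = raster.index_of(cx, cy)
        rows, cols = np.array([r]), np.array([c])
        inside[r, c] = True
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    vals = np.where(inside, raster.values, np.nan)[r0:r1, c0:c1]
    sub = GridRaster(
        values=vals, cell_size=raster.cell_size,
        origin=(raster.origin[0] + c0 * raster.cell_size,
                raster.origin[1] + (raster.nrows - r1) * raster.cell_size),
        role=raster.role)
    z = int(np.sum(~np.isnan(vals)))
    return CircularWindow(raster=sub, z=z, partial=partial)


def _as_values(window) -> np.ndarray:
    if isinstance(window, CircularWindow):
        return window.raster.values
    if isinstance(window, GridRaster):
        return window.values
    return np.asarray(window, float)


def patch_components(window, cls: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected patches of ``cls`` under the 8-neighbour rule.

    Returns ``(labels, areas, perimeters)``: an integer label image
    (0 = background), patch areas in cells, and patch perimeters in cell
    edges.  Perimeter counts rook edges from a patch cell to anything that
    is not the focal class — other classes, nodata, or outside the window.
    """
    vals = _as_values(window)
    mask = vals == cls
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return labels, np.array([], int), np.array([], int)
    areas = np.bincount(labels.ravel())[1:]
    # same-class rook neighbor counts per cell (same 8-patch by construction)
    padded = np.pad(mask, 1, constant_values=False)
    nbrs = (padded[:-2, 1:-1].astype(int) + padded[2:, 1:-1]
            + padded[1:-1, :-2] + padded[1:-1, 2:])
    per_cell = np.where(mask, 4 - nbrs, 0)
    perims = np.bincount(labels.ravel(), weights=per_cell.ravel())[1:]
    return labels, areas.astype(int), perims.astype(int)


def _like_adjacencies(mask: np.ndarray) -> int:
    """Single-count rook adjacencies between focal-class cells."""
    horiz = int(np.sum(mask[:, :-1] & mask[:, 1:]))
    vert = int(np.sum(mask[:-1, :] & mask[1:, :]))
    return horiz + vert


def aggregation_index(window, cls: float = 1.0) -> float:
    """AI = 100 * g / max_g: like-adjacencies relative to the maximum.

    For class area ``a`` with ``n = floor(sqrt(a))`` and ``m = a - n^2``
    the maximum single-count like-adjacency count is ``2n(n-1)`` if m = 0,
    ``2n(n-1) + 2m - 1`` if m <= n, else ``2n(n-1) + 2m - 2``.  Undefined
    (NaN) when the class is absent or a single cell (max_g = 0).
    """
    vals = _as_values(window)
    mask = vals == cls
    a = int(mask.sum())
    if a <= 1:
        return math.nan
    n = int(math.isqrt(a))
    m = a - n * n
    if m == 0:
        max_g = 2 * n * (n - 1)
    elif m <= n:
        max_g = 2 * n * (n - 1) + 2 * m - 1
    else:
        max_g = 2 * n * (n - 1) + 2 * m - 2
    if max_g == 0:
        return math.nan
    return 100.0 * _like_adjacencies(mask) / max_g


def cohesion_index(window, cls: float = 1.0) -> float:
    """Patch cohesion: 100 * [1 - Sum(p) / Sum(p*sqrt(a))] / [1 - 1/sqrt(Z)].

    ``p``/``a`` are per-patch perimeter (cell edges) and area (cells); ``Z``
    is the window's non-nodata cell count.  Undefined when the class is
    absent or Z <= 1.
    """
    vals = _as_values(window)
    z = int(np.sum(~np.isnan(vals)))
    if z <= 1:
        return math.nan
    _, areas, perims = patch_components(vals, cls)
    if areas.size == 0:
        return math.nan
    num = 1.0 - perims.sum() / float(np.sum(perims * np.sqrt(areas)))
    return 100.0 * num / (1.0 - 1.0 / math.sqrt(z))


def clumpiness(window, cls: float = 1.0) -> float:
    """CLUMPY: deviation of like-adjacency proportion from randomness.

    ``G`` is the proportion of adjacencies involving the focal class that
    are like-like, counted from the focal class's side (each like edge seen
    from both cells); ``P`` is the class's proportion of non-nodata cells.
    CLUMPY = (G - P)/P when G < P and P < 0.5, else (G - P)/(1 - P).
    Undefined when P is 0 or 1.  The small-class perimeter correction of
    the reference implementation is deliberately omitted (negligible at
    buffer scale).
    """
    vals = _as_values(window)
    valid = ~np.isnan(vals)
    n_valid = int(valid.sum())
    mask = (vals == cls) & valid
    a = int(mask.sum())
    if n_valid == 0 or a == 0 or a == n_valid:
        return math.nan
    # for each focal cell: rook neighbors that are valid / that are focal
    pad_m = np.pad(mask, 1, constant_values=False)
    pad_v = np.pad(valid, 1, constant_values=False)
    like = np.zeros(vals.shape)
    total = np.zeros(vals.shape)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        like += pad_m[1 + dr:pad_m.shape[0] - 1 + dr,
                      1 + dc:pad_m.shape[1] - 1 + dc]
        total += pad_v[1 + dr:pad_v.shape[0] - 1 + dr,
                       1 + dc:pad_v.shape[1] - 1 + dc]
    like_sum = float(like[mask].sum())
    total_sum = float(total[mask].sum())
    if total_sum == 0:
        return math.nan
    g = like_sum / total_sum
    p = a / n_valid
    if g < p and p < 0.5:
        return (g - p) / p
    return (g - p) / (1.0 - p)


def pafrac(window, cls: float = 1.0) -> float:
    """Perimeter-area fractal dimension: 2 / slope of ln(a) on ln(p).

    Requires at least two patches with unequal ln(perimeter); otherwise
    NaN.  Values near 1 indicate simple (square-like) shapes; values
    approaching 2 indicate highly convoluted perimeters.
    """
    vals = _as_values(window)
    _, areas, perims = patch_components(vals, cls)
    if areas.size < 2:
        return math.nan
    ln_p = np.log(perims.astype(float))
    ln_a = np.log(areas.astype(float))
    if np.allclose(ln_p, ln_p[0]):
        return math.nan
    slope = np.polyfit(ln_p, ln_a, 1)[0]
    if slope == 0:
        return math.nan
    return 2.0 / slope


def connectivity_table(raster: GridRaster, trees: pd.DataFrame,
                       radius: float = 50.0, cls: float = 1.0
                       ) -> pd.DataFrame:
    """Per-tree buffer metrics for the woody class.

    One row per tree: ``tree_id``, ``woody_fraction`` (focal-class share of
    the window's valid cells), the four aggregation metrics, and a
    ``partial`` flag for buffers extending past the raster.  Undefined
    metrics are NaN.
    """
    rows = []
    for _, tr in trees.iterrows():
        win = circular_window(raster, (tr["x"], tr["y"]), radius)
        vals = win.raster.values
        valid = int(np.sum(~np.isnan(vals)))
        woody = int(np.sum(vals == cls))
        rows.append({
            "tree_id": tr["tree_id"],
            "woody_fraction": woody / valid if valid else math.nan,
            "clumpy": clumpiness(win, cls),
            "pafrac": pafrac(win, cls),
            "cohesion": cohesion_index(win, cls),
            "ai": aggregation_index(win, cls),
            "partial": win.partial,
        })
    return pd.DataFrame(rows, columns=["tree_id", "woody_fraction", "clumpy",
                                       "pafrac", "cohesion", "ai", "partial"])
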