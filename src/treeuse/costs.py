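"""Resistance surfaces, least-cost paths, calibration, and the
cost-vs-cohesion regression.

Travel cost across the landscape is modeled on an 8-connected grid graph.
Each cell carries a resistance (cost per meter traversed); the cost of a
move between neighboring cells is the step length (cell size, x sqrt(2)
for diagonals) times the mean of the two endpoint resistances.  A
least-cost path (LCP) is the minimum accumulated-cost route between cells,
found with Dijkstra's algorithm on the sparse grid graph.

Resistance combines land cover and terrain: treed habitat has the base
resistance (1), open ground a higher candidate value (2 = surface A, 8 =
surface B), and slope enters multiplicatively as (1 + slope)^exponent.
Because the true open-ground cost is unknown a priori, it is calibrated
against observed dispersal tracks: the candidate whose modeled LCP lengths
best match the observed cumulative step lengths (smallest mean absolute
error) is selected, ties going to the lower open-ground resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
import statsmodels.api as sm

from .raster import GridRaster

__all__ = [
    "ResistanceSpec",
    "LcpResult",
    "slope_surface",
    "build_cost_surface",
    "least_cost",
    "edge_to_center_cost",
    "calibrate_resistance",
    "cost_vs_cohesion",
    "CostCohesionFit",
]


@dataclass(frozen=True)
class ResistanceSpec:
    """Resistance parameterization of a cost surface.

    ``r_tree`` is the base cost of moving through treed habitat (1 by
    convention); ``r_open`` the open-ground cost (candidate surfaces use 2,
    labelled A, and 8, labelled B); ``slope_exponent`` controls how
    strongly terrain slope inflates cost via (1 + slope)^exponent.
    """

    r_open: float = 2.0
    r_tree: float = 1.0
    slope_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.r_tree < 1 or self.r_open <= 0 or self.slope_exponent < 0:
            raise ValueError("invalid ResistanceSpec parameters")

    @property
    def label(self) -> str:
        if self.r_open == 2:
            return "A"
        if self.r_open == 8:
            return "B"
        return f"r_open={self.r_open:g}"


@dataclass
class LcpResult:
    """Outcome of a least-cost-path query.

    ``accumulated_cost`` is in cost units (resistance x meters); ``path``
    is the cell (row, col) sequence from source to target; ``length_m`` the
    geometric path length.  ``reachable`` is False (costs infinite, path
    empty) when no route exists.
    """

    accumulated_cost: float
    path: list[tuple[int, int]] = field(default_factory=list)
    length_m: float = 0.0
    reachable: bool = True


def slope_surface(dem: GridRaster) -> GridRaster:
    """Per-cell slope (rise/run) from a DEM by Horn's 3x3 method.

    Interior cells use the standard (1,2,1)-weighted central differences;
    edge cells fall back to one-sided differences.  Output role: "slope".
    """
    z = dem.values
    if np.all(np.isnan(z)):
        raise ValueError("DEM contains no data")
    h = dem.cell_size
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float) / (8.0 * h)
    ky = kx.T
    gx = ndi.correlate(z, kx, mode="nearest")
    gy = ndi.correlate(z, ky, mode="nearest")
    # replicate padding halves the span on the border: rescale to one-sided
    gx[:, 0] *= 2.0
    gx[:, -1] *= 2.0
    gy[0, :] *= 2.0
    gy[-1, :] *= 2.0
    return dem.copy(values=np.hypot(gx, gy), role="slope")


def build_cost_surface(habitat: GridRaster, slope: GridRaster,
                       spec: ResistanceSpec) -> GridRaster:
    """Combine habitat and slope into a per-cell resistance raster.

    resistance = (r_tree where habitat == 1 else r_open)
                 * (1 + slope)^slope_exponent.
    Nodata in either input propagates.  Grids must be aligned.
    """
    if not habitat.aligned_with(slope):
        raise ValueError("habitat and slope grids are not aligned")
    base = np.where(habitat.values == 1, spec.r_tree, spec.r_open)
    res = base * (1.0 + slope.values) ** spec.slope_exponent
    res[np.isnan(habitat.values) | np.isnan(slope.values)] = np.nan
    return habitat.copy(values=res, role="resistance")


def _grid_graph(resistance: GridRaster):
    """Sparse 8-connected graph over finite-resistance cells."""
    r = resistance.values
    nrows, ncols = r.shape
    n = nrows * ncols
    finite = np.isfinite(r)
    rows_i, cols_i, weights = [], [], []
    h = resistance.cell_size
    offsets = [(0, 1, h), (1, 0, h), (1, 1, h * math.sqrt(2)),
               (1, -1, h * math.sqrt(2))]
    for dr, dc, dist in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = finite[r0, c0] & finite[r1, c1]
        w = dist * 0.5 * (r[r0, c0] + r[r1, c1])
        rr, cc = np.nonzero(ok)
        a = (rr + r0.start) * ncols + (cc + c0.start)
        b = (rr + r1.start) * ncols + (cc + c1.start)
        rows_i.append(a)
        cols_i.append(b)
        weights.append(w[ok])
    i = np.concatenate(rows_i) if rows_i else np.array([], int)
    j = np.concatenate(cols_i) if cols_i else np.array([], int)
    w = np.concatenate(weights) if weights else np.array([], float)
    return coo_matrix((w, (i, j)), shape=(n, n)).tocsr()


def least_cost(resistance: GridRaster, sources, target: tuple[int, int]
               ) -> LcpResult:
    """Least-cost path from the best of ``sources`` to ``target``.

    ``sources`` is an iterable of (row, col) cells; the result is the
    minimum accumulated cost over all of them, with the corresponding path
    (source first).  An unreachable target yields ``reachable=False`` and
    infinite cost rather than an exception.
    """
    r = resistance.values
    ncols = r.shape[1]
    sources = [tuple(s) for s in sources]
    if not sources:
        raise ValueError("least_cost requires at least one source cell")
    for cell in sources + [tuple(target)]:
        if not np.isfinite(r[cell]):
            raise ValueError(f"cell {cell} is not traversable")
    graph = _grid_graph(resistance)
    t_idx = target[0] * ncols + target[1]
    dist, pred = _dijkstra(graph, directed=False, indices=t_idx,
                           return_predecessors=True)
    src_idx = np.array([s[0] * ncols + s[1] for s in sources])
    costs = dist[src_idx]
    best = int(np.argmin(costs))
    if not np.isfinite(costs[best]):
        return LcpResult(accumulated_cost=math.inf, path=[],
                         length_m=math.nan, reachable=False)
    # walk predecessors from the best source toward the target
    path_idx = [int(src_idx[best])]
    while path_idx[-1] != t_idx:
        path_idx.append(int(pred[path_idx[-1]]))
    path = [(idx // ncols, idx % ncols) for idx in path_idx]
    h = resistance.cell_size
    length = sum(
        h * math.hypot(b[0] - a[0], b[1] - a[1])
        for a, b in zip(path[:-1], path[1:]))
    return LcpResult(accumulated_cost=float(costs[best]), path=path,
                     length_m=length, reachable=True)


def edge_to_center_cost(resistance: GridRaster, tree_xy: tuple[float, float],
                        radius: float = 50.0,
                        window_factor: float = 2.0) -> LcpResult:
    """Minimum accumulated cost from the buffer edge to the tree's cell.

    Source cells are those whose centers fall in the annulus
    (radius - cell_size, radius] around the tree; the target is the cell
    containing the tree.  A tree too close to the raster edge for any
    source cell yields ``reachable=False`` (flagged missing downstream).
    The search is confined to a square window of half-width
    ``window_factor * radius`` around the tree (paths detouring further
    than that around a 50 m buffer would cost more than any direct route).
    """
    if window_factor is not None:
        resistance = _crop(resistance, tree_xy, window_factor * radius)
    target = resistance.index_of(*tree_xy)
    xs, ys = resistance.cell_centers()
    d = np.hypot(xs - tree_xy[0], ys - tree_xy[1])
    ring = (d > radius - resistance.cell_size) & (d <= radius) \
        & np.isfinite(resistance.values)
    sources = list(zip(*np.nonzero(ring)))
    if not sources:
        return LcpResult(accumulated_cost=math.inf, path=[],
                         length_m=math.nan, reachable=False)
    return least_cost(resistance, sources, target)


def _crop(raster: GridRaster, center_xy: tuple[float, float],
          half_width: float) -> GridRaster:
    """Square sub-raster around a point, clipped to the raster bounds."""
    xmin, ymin, xmax, ymax = raster.extent
    x_lo = min(max(center_xy[0] - half_width, xmin), xmax)
    x_hi = min(max(center_xy[0] + half_width, xmin), xmax)
    y_lo = min(max(center_xy[1] - half_width, ymin), ymax)
    y_hi = min(max(center_xy[1] + half_width, ymin), ymax)
    r0, c0 = raster.index_of(x_lo, y_hi)
    r1, c1 = raster.index_of(x_hi, y_lo)
    vals = raster.values[r0:r1 + 1, c0:c1 + 1]
    return GridRaster(
        values=vals, cell_size=raster.cell_size,
        origin=(raster.origin[0] + c0 * raster.cell_size,
                raster.origin[1]
                + (raster.nrows - r1 - 1) * raster.cell_size),
        role=raster.role)


def trajectory_length(track: pd.DataFrame) -> float:
    """Observed cumulative step length (meters) of a fix trajectory."""
    xy = track[["x", "y"]].to_numpy(float)
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def calibrate_resistance(dispersals, habitat: GridRaster, dem: GridRaster,
                         candidates=(ResistanceSpec(r_open=2.0),
                                     ResistanceSpec(r_open=8.0)),
                         ) -> tuple[ResistanceSpec, pd.DataFrame]:
    """Select the resistance candidate best matching dispersal tracks.

    For each candidate, the LCP between every dispersal's start and end fix
    is computed on that candidate's cost surface; the discrepancy is the
    mean absolute difference between modeled LCP length and the observed
    cumulative step length.  Returns the argmin candidate (ties to lower
    ``r_open``) and a per-candidate discrepancy table.
    """
    dispersals = list(dispersals)
    if not dispersals:
        raise ValueError("calibration requires at least one dispersal track")
    slope = slope_surface(dem)
    rows = []
    per_candidate = []
    for spec in sorted(candidates, key=lambda s: s.r_open):
        surface = build_cost_surface(habitat, slope, spec)
        errors = []
        for track in dispersals:
            start = surface.index_of(track["x"].iloc[0], track["y"].iloc[0])
            end = surface.index_of(track["x"].iloc[-1], track["y"].iloc[-1])
            res = least_cost(surface, [start], end)
            if not res.reachable:
                errors.append(math.nan)
                continue
            errors.append(abs(res.length_m - trajectory_length(track)))
        if all(math.isnan(e) for e in errors):
            disc = math.nan
        else:
            disc = float(np.nanmean(errors))
        rows.append({"label": spec.label, "r_open": spec.r_open,
                     "discrepancy_m": disc, "n_paths": len(errors)})
        per_candidate.append((spec, disc))
    table = pd.DataFrame(rows)
    feasible = [(s, d) for s, d in per_candidate if not math.isnan(d)]
    if not feasible:
        raise ValueError("no candidate yields reachable dispersal paths")
    # stable min over r_open-sorted candidates: ties go to lower r_open
    best = min(feasible, key=lambda sd: sd[1])[0]
    return best, table


@dataclass
class CostCohesionFit:
    """OLS fit of fourth-root accumulated cost on cohesion."""

    slope: float
    se: float
    p_value: float
    r2_adj: float
    n: int


def cost_vs_cohesion(costs, cohesion) -> CostCohesionFit:
    """Regress accumulated cost^(1/4) on cohesion by ordinary least squares.

    The fourth-root transform tames the right skew of accumulated costs.
    Pairs with missing values are dropped; at least three complete pairs
    and non-constant cohesion are required.
    """
    df = pd.DataFrame({"cost": np.asarray(costs, float),
                       "cohesion": np.asarray(cohesion, float)}).dropna()
    if (df["cost"] < 0).any():
        raise ValueError("accumulated costs must be non-negative")
    if len(df) < 3:
        raise ValueError("need at least three complete (cost, cohesion) pairs")
    if np.isclose(df["cohesion"].std(ddof=0), 0):
        raise ValueError("cohesion has zero variance")
    y = df["cost"] ** 0.25
    X = sm.add_constant(df["cohesion"])
    fit = sm.OLS(y, X).fit()
    return CostCohesionFit(
        slope=float(fit.params["cohesion"]),
        se=float(fit.bse["cohesion"]),
        p_value=float(fit.pvalues["cohesion"]),
        r2_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )
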