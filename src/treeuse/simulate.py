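"""Synthetic landscapes, trees, koala trajectories and dispersal tracks.

Every generator is a pure function of a :class:`SimConfig`: the seed fully
determines the output, and each stage draws from its own child stream so
regenerating one artifact never perturbs another.

The generator emulates the study system the pipeline is built for: a
fragmented agricultural matrix with isolated open-woodland patches, ~23
GPS-collared animals fixed every 4 h for up to four months, trees varying
in foliar nitrogen (the nutritional-quality axis), FPC concentrations in
the low 0-15 mg/g range, and a handful of dispersers whose ground tracks
follow least-cost routes under a known (true) resistance surface.

Movement is a discrete-time tree-switching process at the fix interval.
When a dwell ends at night the next tree is drawn with log-odds

    beta_n * N_z + beta_n_coh * N_z * cohesion_z - travel_cost * d/100m,

so nitrogen attracts, and attracts *more* where cohesion is low (the
interaction), while distance penalizes.  Day choices weight tree size and
canopy cover (shelter).  Emitted fixes are the occupied tree's coordinates
plus isotropic Gaussian error with per-axis SD = DRMS / sqrt(2).
Between-tree travel is not emitted (the pipeline only consumes fixes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .costs import ResistanceSpec, build_cost_surface, least_cost, slope_surface
from .landscape import connectivity_table
from .raster import GridRaster

__all__ = [
    "SimConfig",
    "generate_landscape",
    "generate_trees",
    "simulate_movement",
    "generate_dispersal",
    "simulate_all",
    "stamp_tree_canopies",
]

_SPECIES = ("E. populnea", "E. albens", "E. dealbata", "E. camaldulensis",
            "E. melliodora", "E. conica", "E. largiflorens")
# Dominant species fixed at 67% of selected trees; the remainder split in
# the study's reported ratios.
_REST = np.array([14.0, 11.0, 9.0, 5.0, 3.0, 0.5])
_SPECIES_P = tuple([0.67] + list(0.33 * _REST / _REST.sum()))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generators."""

    seed: int = 0
    # landscape
    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 5.0
    woody_clustering: float = 0.5   # 0 = salt-and-pepper, 1 = one block
    woody_fraction: float = 0.30
    relief_m: float = 30.0
    # trees
    n_trees: int = 100
    frac_isolated: float = 0.4      # trees scattered in the open matrix
    leaf_n_mean: float = 1.3        # % DM
    leaf_n_sd: float = 0.35
    leaf_n_floor: float = 0.5
    fpc_max: float = 15.0           # mg/g DM
    species_probs: tuple = _SPECIES_P
    # tracking
    n_animals: int = 23
    fix_interval_h: float = 4.0
    duration_days: float = 120.0    # four months
    fix_error_sd: float = 9.05 / math.sqrt(2)  # per-axis, from DRMS 9.05 m
    day_window: tuple[float, float] = (6.0, 18.0)
    tz_offset_h: int = 10
    start_date: str = "2016-04-01"
    # behavior
    beta_n: float = 0.5
    beta_n_coh: float = -0.3
    shelter_w_dbh: float = 0.8
    shelter_w_cover: float = 0.8
    travel_cost: float = 0.3        # log-odds penalty per 100 m
    home_radius_m: float = 250.0
    mean_dwell_h: float = 10.0
    # dispersal
    n_dispersers: int = 5
    true_resistance: ResistanceSpec = ResistanceSpec(r_open=2.0)
    dispersal_fix_step: int = 10    # cells between emitted dispersal fixes

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), stage]))


def generate_landscape(config: SimConfig) -> tuple[GridRaster, GridRaster]:
    """Binary woody habitat + DEM from thresholded smoothed noise.

    The clustering level sets the smoothing length of a Gaussian random
    field which is thresholded at the (1 - woody_fraction) quantile, so
    the woody share is held fixed while aggregation varies from
    salt-and-pepper (0) to a single contiguous block (1).
    """
    rng = config.rng(1)
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    if config.woody_clustering > 0:
        sigma = config.woody_clustering ** 2 * 0.3 * min(config.n_rows,
                                                         config.n_cols)
        fld = gaussian_filter(noise, sigma=sigma, mode="wrap")
    else:
        fld = noise
    thr = np.quantile(fld, 1.0 - config.woody_fraction)
    habitat = GridRaster((fld > thr).astype(float), config.cell_size,
                         role="habitat")
    dem_noise = rng.standard_normal((config.n_rows, config.n_cols))
    dem = gaussian_filter(dem_noise, sigma=0.12 * min(config.n_rows,
                                                      config.n_cols),
                          mode="wrap")
    span = dem.max() - dem.min()
    dem = (dem - dem.min()) / (span if span > 0 else 1.0) * config.relief_m
    return habitat, GridRaster(dem, config.cell_size, role="dem")


def _truncated_normal(rng, mean, sd, floor, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, floor)


def generate_trees(habitat: GridRaster, config: SimConfig) -> pd.DataFrame:
    """Sampled trees inside woody patches and scattered in the matrix.

    Chemistry (leaf N % DM truncated at a floor, FPC within [0, fpc_max]),
    size (DBH, allometric height) and ordinal canopy cover are drawn per
    config; species follow the selected-tree proportions with the dominant
    box species at 67%.
    """
    rng = config.rng(2)
    woody_cells = np.argwhere(habitat.values == 1)
    open_cells = np.argwhere(habitat.values == 0)
    n_iso = int(round(config.n_trees * config.frac_isolated))
    n_in = config.n_trees - n_iso
    if len(woody_cells) < n_in or len(open_cells) < n_iso:
        raise ValueError("not enough cells to place the requested trees")
    chosen = np.concatenate([
        woody_cells[rng.choice(len(woody_cells), n_in, replace=False)],
        open_cells[rng.choice(len(open_cells), n_iso, replace=False)],
    ])
    xs, ys = zip(*(habitat.cell_center(r, c) for r, c in chosen))
    jitter = rng.uniform(-0.4, 0.4, (config.n_trees, 2)) * habitat.cell_size
    dbh = np.clip(rng.lognormal(math.log(40.0), 0.45, config.n_trees),
                  10.0, 150.0)
    height = np.clip(1.3 * dbh ** 0.55 + rng.normal(0, 1.5, config.n_trees),
                     2.0, None)
    cover_latent = ((dbh - dbh.mean()) / dbh.std()
                    + rng.normal(0, 1.0, config.n_trees))
    terciles = np.quantile(cover_latent, [1 / 3, 2 / 3])
    cover = np.where(cover_latent < terciles[0], "low",
                     np.where(cover_latent < terciles[1], "medium", "high"))
    trees = pd.DataFrame({
        "tree_id": [f"T{i:03d}" for i in range(config.n_trees)],
        "x": np.asarray(xs) + jitter[:, 0],
        "y": np.asarray(ys) + jitter[:, 1],
        "species": rng.choice(_SPECIES, config.n_trees,
                              p=config.species_probs),
        "dbh_cm": dbh,
        "height_m": height,
        "cover": cover,
        "leaf_n_pct": _truncated_normal(rng, config.leaf_n_mean,
                                        config.leaf_n_sd,
                                        config.leaf_n_floor, config.n_trees),
        "fpc_mg_g": rng.beta(1.2, 2.5, config.n_trees) * config.fpc_max,
    })
    return trees


def stamp_tree_canopies(habitat: GridRaster, trees: pd.DataFrame
                        ) -> GridRaster:
    """Mark each sampled tree's own canopy cell as woody habitat.

    A woody-extent layer built from canopy height maps trees taller than a
    couple of meters, so every sampled tree contributes at least its own
    cell of woody cover; without this, an isolated paddock tree would sit
    in an all-open buffer and its connectivity would be undefined rather
    than merely low.
    """
    out = habitat.copy()
    for _, tr in trees.iterrows():
        out.values[out.index_of(tr["x"], tr["y"])] = 1.0
    return out


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    v = np.where(np.isnan(v), np.nanmean(v) if np.isfinite(np.nanmean(v))
                 else 0.0, v)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def simulate_movement(trees: pd.DataFrame, habitat: GridRaster,
                      config: SimConfig,
                      cohesion: np.ndarray | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fixes for every animal; return (fixes, true_visits).

    ``true_visits`` records the exact occupancy schedule (animal, tree,
    arrival/departure timestamps, dwell in fixes) before GPS error is
    applied, for ground-truth comparisons.
    """
    rng = config.rng(3)
    if cohesion is None:
        cohesion = connectivity_table(habitat, trees)["cohesion"].to_numpy()
    z_n = _zscore(trees["leaf_n_pct"].to_numpy())
    z_coh = _zscore(cohesion)
    z_dbh = _zscore(trees["dbh_cm"].to_numpy())
    cover_num = trees["cover"].map({"low": 0.0, "medium": 1.0,
                                    "high": 2.0}).to_numpy() - 1.0
    xy = trees[["x", "y"]].to_numpy(float)
    n_epochs = int(config.duration_days * 24 / config.fix_interval_h)
    start = (pd.Timestamp(config.start_date)
             .tz_localize(f"UTC+{config.tz_offset_h:02d}:00"))
    times = start + pd.to_timedelta(
        np.arange(n_epochs) * config.fix_interval_h, unit="h")
    # fixed UTC offset, no DST: wall-clock hour advances linearly
    hours = (start.hour + start.minute / 60.0
             + np.arange(n_epochs) * config.fix_interval_h) % 24.0
    is_day = (hours >= config.day_window[0]) & (hours < config.day_window[1])
    mean_dwell_epochs = config.mean_dwell_h / config.fix_interval_h

    fix_rows = []
    visit_rows = []
    for a in range(config.n_animals):
        animal = f"K{a:02d}"
        center = xy[rng.integers(len(trees))]
        d_center = np.hypot(*(xy - center).T)
        radius = config.home_radius_m
        cand = np.flatnonzero(d_center <= radius)
        while len(cand) < 5:
            radius *= 1.5
            cand = np.flatnonzero(d_center <= radius)
        cur = int(rng.choice(cand))
        dwell = max(1, int(np.ceil(rng.gamma(2.0, mean_dwell_epochs / 2.0))))
        arrival = 0
        occupancy = np.empty(n_epochs, dtype=int)
        for e in range(n_epochs):
            if dwell == 0:
                others = cand[cand != cur]
                dist = np.hypot(*(xy[others] - xy[cur]).T)
                if is_day[e]:
                    logw = (config.shelter_w_dbh * z_dbh[others]
                            + config.shelter_w_cover * cover_num[others])
                else:
                    logw = (config.beta_n * z_n[others]
                            + config.beta_n_coh * z_n[others] * z_coh[others])
                logw = logw - config.travel_cost * dist / 100.0
                w = np.exp(logw - logw.max())
                nxt = int(rng.choice(others, p=w / w.sum()))
                visit_rows.append((animal, trees["tree_id"].iloc[cur],
                                   times[arrival], times[e - 1], e - arrival))
                cur = nxt
                arrival = e
                dwell = max(1, int(np.ceil(
                    rng.gamma(2.0, mean_dwell_epochs / 2.0))))
            occupancy[e] = cur
            dwell -= 1
        visit_rows.append((animal, trees["tree_id"].iloc[cur],
                           times[arrival], times[n_epochs - 1],
                           n_epochs - arrival))
        err = rng.normal(0.0, config.fix_error_sd, (n_epochs, 2))
        pos = xy[occupancy] + err
        fix_rows.append(pd.DataFrame({
            "animal_id": animal, "t": times,
            "x": pos[:, 0], "y": pos[:, 1],
            "true_tree_id": trees["tree_id"].to_numpy()[occupancy],
        }))
    fixes = pd.concat(fix_rows, ignore_index=True)
    true_visits = pd.DataFrame(
        visit_rows, columns=["animal_id", "tree_id", "start_t", "end_t",
                             "n_fixes"])
    return fixes, true_visits


def generate_dispersal(habitat: GridRaster, dem: GridRaster,
                       config: SimConfig,
                       spec: ResistanceSpec | None = None,
                       ) -> list[pd.DataFrame]:
    """Dispersal tracks following least-cost routes under the true spec.

    Each disperser starts on a woody cell in the western quarter of the
    landscape and ends on one in the eastern quarter; its emitted fixes
    subsample the LCP every ``dispersal_fix_step`` cells with GPS jitter.
    Unreachable endpoint pairs are resampled.
    """
    rng = config.rng(4)
    spec = spec or config.true_resistance
    surface = build_cost_surface(habitat, slope_surface(dem), spec)
    ncols = habitat.ncols
    woody = np.argwhere(habitat.values == 1)
    west = woody[woody[:, 1] < ncols // 4]
    east = woody[woody[:, 1] >= 3 * ncols // 4]
    if len(west) == 0 or len(east) == 0:
        raise ValueError("landscape has no woody cells in one half")
    start_t = (pd.Timestamp(config.start_date)
               .tz_localize(f"UTC+{config.tz_offset_h:02d}:00"))
    tracks = []
    for d in range(config.n_dispersers):
        for _ in range(50):
            s = tuple(west[rng.integers(len(west))])
            t = tuple(east[rng.integers(len(east))])
            res = least_cost(surface, [s], t)
            if res.reachable:
                break
        else:
            raise ValueError("could not find a reachable dispersal route")
        idx = list(range(0, len(res.path), config.dispersal_fix_step))
        if idx[-1] != len(res.path) - 1:
            idx.append(len(res.path) - 1)
        cells = [res.path[i] for i in idx]
        coords = np.array([habitat.cell_center(r, c) for r, c in cells])
        coords = coords + rng.normal(0.0, config.fix_error_sd,
                                     coords.shape)
        xmin, ymin, xmax, ymax = habitat.extent
        pad = 0.01 * habitat.cell_size
        coords[:, 0] = np.clip(coords[:, 0], xmin + pad, xmax - pad)
        coords[:, 1] = np.clip(coords[:, 1], ymin + pad, ymax - pad)
        tracks.append(pd.DataFrame({
            "animal_id": f"D{d:02d}",
            "t": start_t + pd.to_timedelta(
                np.arange(len(cells)) * config.fix_interval_h, unit="h"),
            "x": coords[:, 0], "y": coords[:, 1],
        }))
    return tracks


def simulate_all(config: SimConfig) -> dict:
    """Run every generator; return all artifacts plus the ground truth."""
    habitat, dem = generate_landscape(config)
    trees = generate_trees(habitat, config)
    habitat = stamp_tree_canopies(habitat, trees)
    conn = connectivity_table(habitat, trees)
    fixes, true_visits = simulate_movement(
        trees, habitat, config, cohesion=conn["cohesion"].to_numpy())
    dispersals = generate_dispersal(habitat, dem, config)
    truth = {
        "beta_n": config.beta_n,
        "beta_n_coh": config.beta_n_coh,
        "true_r_open": config.true_resistance.r_open,
        "seed": config.seed,
    }
    return {"habitat": habitat, "dem": dem, "trees": trees,
            "connectivity": conn, "fixes": fixes,
            "true_visits": true_visits, "dispersals": dispersals,
            "truth": truth}
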