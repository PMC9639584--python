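"""End-to-end pipeline: segment -> metrics -> connectivity -> LCP -> infer.

:func:`run_pipeline` chains the analysis stages, writing each stage's
table to the output directory so intermediates can be inspected (and
regenerated identically, since every stage is deterministic for a fixed
config).  A ``provenance.json`` records the full configuration, package
and library versions, the seed and the config hash; every CSV carries the
hash in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .costs import (ResistanceSpec, build_cost_surface, calibrate_resistance,
                    cost_vs_cohesion, edge_to_center_cost, slope_surface)
from .inference import (DEFAULT_INTERACTION, DEFAULT_PREDICTORS, averaged_table,
                        build_candidate_set, confidence_set, fit_candidate_set,
                        model_average, model_table, standardize_predictors)
from .io import read_ascii_grid, read_fixes, read_trees, write_table
from .landscape import connectivity_table
from .trajectory import (assign_fixes_to_trees, segment_visits,
                         truncate_tracking, visit_metrics)

__all__ = ["RunConfig", "run_pipeline", "build_analysis_table"]

log = logging.getLogger("treeuse")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults mirror the study protocol: 5 m tree buffers, visits of at
    least two consecutive fixes ended by more than two out-of-buffer
    records, a 50 m connectivity buffer, open-ground resistance candidates
    2 and 8 over a base cost of 1, and a delta-AICc threshold of 2 for the
    confidence set.
    """

    fixes_path: str = ""
    trees_path: str = ""
    habitat_path: str = ""
    dem_path: str = ""
    out_dir: str = "treeuse_out"
    buffer_radius: float = 5.0
    min_run: int = 2
    max_gap: int = 2
    connectivity_radius: float = 50.0
    day_window: tuple[float, float] = (6.0, 18.0)
    max_duration_days: float = 120.0
    resistance_candidates: tuple[float, ...] = (2.0, 8.0)
    slope_exponent: float = 1.0
    delta_threshold: float = 2.0
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    interaction: tuple[str, str] | None = DEFAULT_INTERACTION
    responses: tuple[str, ...] = ("revisits", "rt", "ttor")
    periods: tuple[str, ...] = ("night", "day")
    averaging: str = "natural"
    dispersals_path: str = ""
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for tup in ("day_window", "resistance_candidates", "predictors",
                    "interaction", "responses", "periods"):
            v = getattr(cfg, tup)
            if isinstance(v, list):
                setattr(cfg, tup, tuple(v))
        return cfg

    def hash(self) -> str:
        """Digest of the analysis parameters (not input/output locations)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "fixes_path", "trees_path", "habitat_path",
                    "dem_path", "dispersals_path"):
            payload.pop(key, None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()
                              ).hexdigest()[:12]


_PREDICTOR_SOURCE = {"dbh": "dbh_cm", "height": "height_m", "cover": "cover",
                     "leaf_n": "leaf_n_pct", "connectivity": "cohesion"}


def _availability_zeros(metrics: pd.DataFrame, trees: pd.DataFrame,
                        fixes: pd.DataFrame,
                        quantile: float = 0.95) -> pd.DataFrame:
    """Zero-count rows for trees available to, but unvisited by, an animal.

    A tree is *available* to an animal if it lies within the animal's
    observed range — the ``quantile`` radius of its fixes about their
    median center.  Visit-count models need these structural zeros: a
    table restricted to visited trees truncates the response and biases
    effects toward zero.
    """
    periods = metrics["period"].unique() if len(metrics) else ["all"]
    rows = []
    for animal, grp in fixes.groupby("animal_id", sort=False):
        cx, cy = grp["x"].median(), grp["y"].median()
        radius = np.quantile(np.hypot(grp["x"] - cx, grp["y"] - cy),
                             quantile)
        d = np.hypot(trees["x"] - cx, trees["y"] - cy)
        available = set(trees["tree_id"][d <= radius])
        visited = set(metrics.loc[metrics["animal_id"] == animal, "tree_id"])
        for tree in sorted(available - visited):
            for period in periods:
                rows.append({"animal_id": animal, "tree_id": tree,
                             "period": period, "n_visits": 0,
                             "mean_rt_h": np.nan, "mean_ttor_h": np.nan})
    return pd.DataFrame(rows, columns=metrics.columns)


def build_analysis_table(metrics: pd.DataFrame, trees: pd.DataFrame,
                         connectivity: pd.DataFrame,
                         predictors=DEFAULT_PREDICTORS,
                         fixes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge use metrics with tree attributes and buffer connectivity.

    One row per animal x tree x period; predictor columns are renamed to
    their model names (dbh, height, cover, leaf_n, connectivity) and
    standardized over the merged table.  When ``fixes`` are supplied,
    zero-visit rows are added for trees inside an animal's observed range
    that it never visited (see :func:`_availability_zeros`).
    """
    if fixes is not None:
        metrics = pd.concat(
            [metrics, _availability_zeros(metrics, trees, fixes)],
            ignore_index=True)
    tr = trees.merge(connectivity[["tree_id", "cohesion"]], on="tree_id",
                     how="left")
    tab = metrics.merge(tr, on="tree_id", how="left")
    for name, src in _PREDICTOR_SOURCE.items():
        if src in tab.columns and name != src:
            tab = tab.rename(columns={src: name})
    return standardize_predictors(tab, [p for p in predictors
                                        if p in tab.columns])


def run_pipeline(config: RunConfig, inputs: dict | None = None) -> dict:
    """Execute the full chain and write artifacts under ``config.out_dir``.

    ``inputs`` may supply in-memory objects (keys ``fixes``, ``trees``,
    ``habitat``, ``dem``, ``dispersals``) instead of file paths.  Returns a
    dict of the principal in-memory results.
    """
    inputs = inputs or {}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    fixes = inputs.get("fixes")
    if fixes is None:
        fixes = read_fixes(config.fixes_path)
    trees = inputs.get("trees")
    if trees is None:
        trees = read_trees(config.trees_path)
    habitat = inputs.get("habitat")
    if habitat is None:
        habitat = read_ascii_grid(config.habitat_path, role="habitat")
    dem = inputs.get("dem")
    if dem is None:
        dem = read_ascii_grid(config.dem_path, role="dem")

    # -- stage 1: visits and use metrics ---------------------------------
    fixes = truncate_tracking(
        fixes, pd.Timedelta(days=config.max_duration_days))
    labeled = assign_fixes_to_trees(fixes, trees, config.buffer_radius)
    visits = segment_visits(labeled, config.min_run, config.max_gap,
                            config.day_window)
    metrics = visit_metrics(visits)
    write_table(visits, out / "visits.csv", chash)
    write_table(metrics, out / "use_metrics.csv", chash)
    log.info("segmented %d visits from %d fixes", len(visits), len(fixes))

    # -- stage 2: buffer connectivity metrics ----------------------------
    conn = connectivity_table(habitat, trees, config.connectivity_radius)
    write_table(conn, out / "connectivity.csv", chash)

    # -- stage 3: resistance calibration + accumulated costs -------------
    slope = slope_surface(dem)
    candidates = [ResistanceSpec(r_open=r, slope_exponent=config.slope_exponent)
                  for r in config.resistance_candidates]
    dispersals = inputs.get("dispersals")
    if dispersals is None and config.dispersals_path:
        disp_df = read_fixes(config.dispersals_path)
        dispersals = [g for _, g in disp_df.groupby("animal_id", sort=False)]
    if dispersals:
        chosen, calib = calibrate_resistance(dispersals, habitat, dem,
                                             candidates)
        write_table(calib, out / "calibration.csv", chash)
    else:
        chosen = candidates[0]
        calib = None
    surface = build_cost_surface(habitat, slope, chosen)
    lcp_rows = []
    for _, tr in trees.iterrows():
        res = edge_to_center_cost(surface, (tr["x"], tr["y"]),
                                  config.connectivity_radius)
        lcp_rows.append({"tree_id": tr["tree_id"],
                         "accumulated_cost": res.accumulated_cost
                         if res.reachable else np.nan,
                         "path_length_m": res.length_m,
                         "reachable": res.reachable})
    lcp = pd.DataFrame(lcp_rows)
    write_table(lcp, out / "lcp_costs.csv", chash)

    cc = lcp.merge(conn[["tree_id", "cohesion"]], on="tree_id")
    try:
        cc_fit = cost_vs_cohesion(cc["accumulated_cost"], cc["cohesion"])
        write_table(pd.DataFrame([dataclasses.asdict(cc_fit)]),
                    out / "cost_vs_cohesion.csv", chash)
    except ValueError as exc:
        log.warning("cost-vs-cohesion fit skipped: %s", exc)
        cc_fit = None

    # -- stage 4: multimodel inference ------------------------------------
    table = build_analysis_table(metrics, trees, conn, config.predictors,
                                 fixes=fixes)
    candidates_terms = build_candidate_set(config.predictors,
                                           config.interaction)
    models: dict[tuple[str, str], list] = {}
    averaged: dict[tuple[str, str], list] = {}
    for period in config.periods:
        sub = table[table["period"] == period]
        for response in config.responses:
            try:
                ranked = fit_candidate_set(sub, response,
                                           candidates=candidates_terms)
            except (ValueError, KeyError) as exc:
                log.warning("skipping %s/%s models: %s", period, response,
                            exc)
                continue
            cset = confidence_set(ranked, config.delta_threshold)
            avg = model_average(cset, method=config.averaging)
            models[(period, response)] = ranked
            averaged[(period, response)] = avg
            write_table(model_table(ranked),
                        out / f"models_{period}_{response}.csv", chash)
            write_table(averaged_table(avg),
                        out / f"averaged_{period}_{response}.csv", chash)

    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "versions": {"treeuse": __version__,
                     "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))
    return {"visits": visits, "metrics": metrics, "connectivity": conn,
            "lcp": lcp, "chosen_resistance": chosen, "calibration": calib,
            "cost_vs_cohesion": cc_fit, "models": models,
            "averaged": averaged, "analysis_table": table}
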