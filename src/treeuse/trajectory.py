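"""GPS-fix processing: tree-buffer assignment, visit segmentation, and
revisitation metrics.

The central objects are plain :class:`pandas.DataFrame` tables:

* **fixes** — one row per GPS fix: ``animal_id``, ``t`` (timezone-aware
  timestamp carrying the local UTC offset), ``x``, ``y`` (projected meters).
* **trees** — one row per sampled tree: ``tree_id``, ``x``, ``y`` plus
  physical/chemical attributes (``species``, ``dbh_cm``, ``height_m``,
  ``cover``, ``leaf_n_pct``, ``fpc_mg_g``).
* **visits** — one row per visit: ``animal_id``, ``tree_id``, ``start_t``,
  ``end_t``, ``n_fixes``, ``diel_fraction_day``.

A *visit* starts when an animal is recorded inside a tree's buffer for at
least ``min_run`` consecutive fixes and ends when the animal is recorded
outside that buffer for more than ``max_gap`` consecutive fixes (a fix
recorded inside a *different* tree's buffer ends the visit immediately, so
one animal's visits never overlap in time).  Revisitation is summarized per
animal x tree x diel period as the visit count, the mean residence time
(RT) and the mean time-to-return (TtoR, the gap from the end of one visit
to the start of the next).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "assign_fixes_to_trees",
    "segment_visits",
    "visit_metrics",
    "classify_diel",
    "drms",
    "tree_height",
    "truncate_tracking",
    "DAY_WINDOW",
]

#: Default diel day window, local time, half-open: [06:00, 18:00).
DAY_WINDOW: tuple[float, float] = (6.0, 18.0)


def _require_tz(t: pd.Series | pd.DatetimeIndex) -> None:
    tz = getattr(t.dtype, "tz", None)
    if tz is None:
        raise ValueError(
            "timestamps must be timezone-aware (local UTC offset is needed "
            "for diel classification)")


def _check_monotone(fixes: pd.DataFrame) -> None:
    for animal, grp in fixes.groupby("animal_id", sort=False):
        dt = grp["t"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            bad = grp.index[1:][(dt <= pd.Timedelta(0)).to_numpy()]
            raise ValueError(
                f"fixes for animal {animal!r} are not strictly increasing in "
                f"time (rows {list(bad[:5])})")


def assign_fixes_to_trees(fixes: pd.DataFrame, trees: pd.DataFrame,
                          buffer_radius: float = 5.0) -> pd.DataFrame:
    """Label each fix with the tree whose buffer contains it, if any.

    A fix is labeled with a tree iff its Euclidean distance to that tree is
    <= ``buffer_radius``.  Where buffers overlap the nearest tree wins;
    exact distance ties break to the smallest ``tree_id``.  Fixes outside
    every buffer get label ``None``.

    Returns a copy of ``fixes`` with a ``tree_id`` object column appended.
    """
    if not buffer_radius > 0:
        raise ValueError("buffer_radius must be positive")
    out = fixes.copy()
    if len(trees) == 0:
        out["tree_id"] = None
        return out
    # sort trees by id so argmin's first-wins rule breaks ties to smallest id
    tr = trees.sort_values("tree_id").reset_index(drop=True)
    tree_xy = tr[["x", "y"]].to_numpy(float)
    fix_xy = out[["x", "y"]].to_numpy(float)
    labels = np.full(len(out), None, dtype=object)
    # KD-tree prefilter, exact distance comparison for the candidates
    kdt = cKDTree(tree_xy)
    cand = kdt.query_ball_point(fix_xy, r=buffer_radius)
    for i, idxs in enumerate(cand):
        if not idxs:
            continue
        d2 = np.sum((tree_xy[idxs] - fix_xy[i]) ** 2, axis=1)
        order = np.argsort(idxs)  # ascending tree order among candidates
        d2 = d2[order]
        idxs = np.asarray(idxs)[order]
        labels[i] = tr["tree_id"].iloc[idxs[int(np.argmin(d2))]]
    out["tree_id"] = labels
    return out


def segment_visits(labeled_fixes: pd.DataFrame, min_run: int = 2,
                   max_gap: int = 2,
                   day_window: tuple[float, float] = DAY_WINDOW,
                   ) -> pd.DataFrame:
    """Segment labeled fixes into per-tree visits.

    For each animal and tree, maximal runs of that tree's label separated by
    at most ``max_gap`` consecutive fixes recorded *outside every buffer*
    are merged into one visit; a fix recorded at a different tree always
    terminates the run.  Merged runs with at least ``min_run`` in-buffer
    fixes become visits; ``start_t``/``end_t`` are the first/last in-buffer
    fix times.  GPS dropouts (missing fixes) widen elapsed time but do not
    count as out-of-buffer records.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    _require_tz(labeled_fixes["t"])
    _check_monotone(labeled_fixes)

    rows = []
    for animal, grp in labeled_fixes.groupby("animal_id", sort=False):
        grp = grp.reset_index(drop=True)
        labels = grp["tree_id"].to_numpy(object)
        times = grp["t"].to_numpy()
        is_day = classify_diel(grp["t"], day_window) == "day"
        for tree in pd.unique(labels[pd.notna(labels)]):
            pos = np.flatnonzero(labels == tree)
            clusters: list[list[int]] = [[int(pos[0])]]
            for prev, cur in zip(pos[:-1], pos[1:]):
                between = labels[prev + 1:cur]
                n_out = len(between)
                saw_other_tree = any(pd.notna(b) for b in between)
                if n_out <= max_gap and not saw_other_tree:
                    clusters[-1].append(int(cur))
                else:
                    clusters.append([int(cur)])
            for cl in clusters:
                if len(cl) < min_run:
                    continue
                day_frac = float(np.mean(is_day.to_numpy()[cl]))
                rows.append({
                    "animal_id": animal,
                    "tree_id": tree,
                    "start_t": grp["t"].iloc[cl[0]],
                    "end_t": grp["t"].iloc[cl[-1]],
                    "n_fixes": len(cl),
                    "diel_fraction_day": day_frac,
                })
    visits = pd.DataFrame(
        rows, columns=["animal_id", "tree_id", "start_t", "end_t",
                       "n_fixes", "diel_fraction_day"])
    if len(visits):
        visits = visits.sort_values(
            ["animal_id", "start_t"], kind="stable").reset_index(drop=True)
    return visits


def _period_mask(visits: pd.DataFrame, period: str) -> pd.Series:
    if period == "all":
        return pd.Series(True, index=visits.index)
    if period == "day":
        return visits["diel_fraction_day"] > 0.5
    if period == "night":
        return visits["diel_fraction_day"] <= 0.5
    raise ValueError(f"unknown period {period!r}")


def visit_metrics(visits: pd.DataFrame,
                  periods: Sequence[str] = ("day", "night", "all"),
                  ) -> pd.DataFrame:
    """Per animal x tree x period revisitation metrics.

    ``n_visits`` counts visits assigned to the period (a visit is "day" iff
    more than half of its fixes fall in the day window).  ``mean_rt_h`` is
    the mean visit duration in hours; ``mean_ttor_h`` the mean gap, end of
    one visit to start of the next, over consecutive visit pairs within the
    period.  Metrics that are undefined (no visits for RT; fewer than two
    for TtoR) are NaN, never zero.  Rows cover every animal-tree pair with
    at least one visit overall, for every requested period.
    """
    cols = ["animal_id", "tree_id", "period", "n_visits",
            "mean_rt_h", "mean_ttor_h"]
    if len(visits) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for (animal, tree), grp in visits.groupby(["animal_id", "tree_id"],
                                              sort=False):
        grp = grp.sort_values("start_t")
        for period in periods:
            sub = grp[_period_mask(grp, period)]
            n = len(sub)
            if n:
                durations = (sub["end_t"] - sub["start_t"]
                             ).dt.total_seconds() / 3600.0
                mean_rt = float(durations.mean())
            else:
                mean_rt = math.nan
            if n >= 2:
                gaps = (sub["start_t"].iloc[1:].to_numpy()
                        - sub["end_t"].iloc[:-1].to_numpy())
                mean_ttor = float(pd.Series(gaps).dt.total_seconds().mean()
                                  / 3600.0)
            else:
                mean_ttor = math.nan
            rows.append({"animal_id": animal, "tree_id": tree,
                         "period": period, "n_visits": n,
                         "mean_rt_h": mean_rt, "mean_ttor_h": mean_ttor})
    return pd.DataFrame(rows, columns=cols)


def classify_diel(t, day_window: tuple[float, float] = DAY_WINDOW):
    """Classify timestamps as "day" or "night" by local wall-clock time.

    The day window is half-open: a time equal to the upper bound is night.
    Timestamps must be timezone-aware; the wall-clock in their own zone
    (i.e. the local offset they carry) is used.
    """
    lo, hi = day_window
    if isinstance(t, (pd.Series, pd.DatetimeIndex)):
        _require_tz(t)
        tt = t.dt if isinstance(t, pd.Series) else t
        hours = tt.hour + tt.minute / 60.0 + tt.second / 3600.0
        out = np.where((hours >= lo) & (hours < hi), "day", "night")
        return pd.Series(out, index=t.index) if isinstance(t, pd.Series) \
            else np.asarray(out)
    ts = pd.Timestamp(t)
    if ts.tz is None:
        raise ValueError("timestamp lacks a timezone/local offset")
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return "day" if lo <= hour < hi else "night"


def drms(fixes: pd.DataFrame | np.ndarray,
         reference: tuple[float, float]) -> float:
    """Distance root-mean-square error of fixes about a reference point.

    ``sqrt(mean(d_i^2))`` over Euclidean distances from each fix to the
    reference — the standard static-test accuracy statistic for a GPS unit.
    """
    if isinstance(fixes, pd.DataFrame):
        xy = fixes[["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(fixes, float).reshape(-1, 2)
    if xy.shape[0] == 0:
        raise ValueError("drms requires at least one fix")
    d2 = np.sum((xy - np.asarray(reference, float)) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def tree_height(top_distance: float, base_distance: float,
                observer_height: float = 0.0) -> float:
    """Tree height from rangefinder distances by right-triangle geometry.

    The observer measures the slant distance to the treetop and the
    horizontal distance to the trunk base; the vertical leg is
    ``sqrt(top^2 - base^2)``, to which the observer's eye height is added.
    """
    if base_distance < 0:
        raise ValueError("base_distance must be >= 0")
    if not top_distance > base_distance:
        raise ValueError("top_distance must exceed base_distance")
    return math.sqrt(top_distance ** 2 - base_distance ** 2) + observer_height


def truncate_tracking(fixes: pd.DataFrame,
                      max_duration: pd.Timedelta = pd.Timedelta(days=120),
                      ) -> pd.DataFrame:
    """Keep at most ``max_duration`` of movement data per animal.

    Tracking windows longer than the cap are truncated from each animal's
    first fix, so every animal contributes a comparable monitoring span
    (default four months).
    """
    _check_monotone(fixes)
    keep = []
    for _, grp in fixes.groupby("animal_id", sort=False):
        t0 = grp["t"].iloc[0]
        keep.append(grp[grp["t"] <= t0 + max_duration])
    return pd.concat(keep, ignore_index=True) if keep else fixes.copy()
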