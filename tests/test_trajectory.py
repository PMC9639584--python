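"""Visit segmentation, revisitation metrics, and fix-level utilities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treeuse.trajectory import (DAY_WINDOW, assign_fixes_to_trees,
                                classify_diel, drms, segment_visits,
                                tree_height, truncate_tracking, visit_metrics)

from conftest import T0, STEP, TZ, labeled_frame


# ---------------------------------------------------------------------------
# independent run-merge oracle: explicit run-list representation
# ---------------------------------------------------------------------------

def oracle_segments(labels, min_run=2, max_gap=2):
    """Reference segmentation via explicit run-length encoding.

    Encode the label string as (symbol, start, length) runs; for each tree
    merge consecutive runs of that tree when every intervening run is a
    None-run and the intervening fixes total <= max_gap; keep merged
    groups with enough in-buffer fixes.  Returns {(tree, first_index,
    last_index, n_fixes)}.
    """
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j - i))
        i = j
    out = set()
    trees = {sym for sym, _, _ in runs if sym is not None}
    for tree in trees:
        tree_runs = [k for k, (sym, _, _) in enumerate(runs) if sym == tree]
        groups = [[tree_runs[0]]]
        for prev, cur in zip(tree_runs, tree_runs[1:]):
            between = runs[prev + 1:cur]
            gap = sum(length for _, _, length in between)
            only_none = all(sym is None for sym, _, _ in between)
            if only_none and gap <= max_gap:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        for grp in groups:
            n_fixes = sum(runs[k][2] for k in grp)
            if n_fixes >= min_run:
                first = runs[grp[0]][1]
                last = runs[grp[-1]][1] + runs[grp[-1]][2] - 1
                out.add((tree, first, last, n_fixes))
    return out


def as_tuples(visits, start=T0, step=STEP):
    return {(v.tree_id,
             int((v.start_t - start) / step),
             int((v.end_t - start) / step),
             v.n_fixes)
            for v in visits.itertuples()}


class TestSegmentVisits:
    def test_single_run_with_trailing_absence(self):
        visits = segment_visits(labeled_frame(["A", "A", "A"] + [None] * 4))
        assert as_tuples(visits) == {("A", 0, 2, 3)}
        # two fix-intervals = 8 h duration
        dur = (visits["end_t"] - visits["start_t"]).iloc[0]
        assert dur == 2 * STEP

    def test_isolated_single_fixes_make_no_visit(self):
        visits = segment_visits(labeled_frame(["A", None, None, None, "A"]))
        assert len(visits) == 0

    def test_gap_at_threshold_merges_gap_above_splits(self):
        merged = segment_visits(
            labeled_frame(["A", "A", None, None, "A", "A"]))
        assert as_tuples(merged) == {("A", 0, 5, 4)}
        split = segment_visits(
            labeled_frame(["A", "A", None, None, None, "A", "A"]))
        assert as_tuples(split) == {("A", 0, 1, 2), ("A", 5, 6, 2)}

    def test_other_tree_fix_ends_the_visit(self):
        # a recorded relocation to B breaks A's run even though gap <= max_gap
        visits = segment_visits(labeled_frame(["A", "A", "B", "B", "A", "A"]))
        assert as_tuples(visits) == {("A", 0, 1, 2), ("B", 2, 3, 2),
                                     ("A", 4, 5, 2)}

    def test_visits_never_overlap_within_animal(self):
        rng = np.random.default_rng(42)
        alphabet = ["A", "B", None]
        for _ in range(300):
            labels = list(rng.choice(alphabet, size=rng.integers(2, 40)))
            visits = segment_visits(labeled_frame(labels))
            for animal, grp in visits.groupby("animal_id"):
                grp = grp.sort_values("start_t")
                starts = grp["start_t"].to_numpy()
                ends = grp["end_t"].to_numpy()
                assert (starts[1:] > ends[:-1]).all()
            assert visits["n_fixes"].sum() <= len(labels)

    @settings(derandomize=True, max_examples=400, deadline=None)
    @given(st.lists(st.sampled_from(["A", "B", None]), min_size=1,
                    max_size=50),
           st.integers(1, 3), st.integers(0, 3))
    def test_matches_run_merge_oracle(self, labels, min_run, max_gap):
        visits = segment_visits(labeled_frame(labels), min_run, max_gap)
        assert as_tuples(visits) == oracle_segments(labels, min_run, max_gap)

    def test_rejects_unordered_timestamps(self):
        frame = labeled_frame(["A", "A", "A"])
        frame.loc[2, "t"] = frame.loc[0, "t"]
        with pytest.raises(ValueError, match="increasing"):
            segment_visits(frame)

    def test_buffer_radius_monotonicity(self, toy_trees):
        rng = np.random.default_rng(7)
        n = 200
        fixes = pd.DataFrame({
            "animal_id": "K1",
            "t": [T0 + i * STEP for i in range(n)],
            "x": rng.uniform(-20, 120, n),
            "y": rng.uniform(-20, 100, n),
        })
        counts = {}
        for radius in (5.0, 10.0, 20.0):
            labeled = assign_fixes_to_trees(fixes, toy_trees, radius)
            visits = segment_visits(labeled)
            counts[radius] = visits.groupby("tree_id").size()
        for small, large in ((5.0, 10.0), (10.0, 20.0)):
            merged = pd.concat([counts[small], counts[large]], axis=1,
                               keys=["s", "l"]).fillna(0)
            assert (merged["l"] >= merged["s"]).all()


class TestAssignFixes:
    def test_inside_single_buffer(self, toy_trees):
        fixes = pd.DataFrame({"animal_id": "K1", "t": [T0],
                              "x": [3.0], "y": [0.0]})
        assert assign_fixes_to_trees(fixes, toy_trees, 5.0
                                     )["tree_id"].iloc[0] == "A"

    def test_outside_all_buffers(self, toy_trees):
        fixes = pd.DataFrame({"animal_id": "K1", "t": [T0],
                              "x": [50.0], "y": [40.0]})
        assert assign_fixes_to_trees(fixes, toy_trees, 5.0
                                     )["tree_id"].iloc[0] is None

    def test_overlapping_buffers_nearest_wins(self):
        trees = pd.DataFrame({"tree_id": ["A", "B"], "x": [0.0, 8.5],
                              "y": [0.0, 0.0]})
        fixes = pd.DataFrame({"animal_id": "K1", "t": [T0],
                              "x": [4.0], "y": [0.0]})
        # 4.0 from A, 4.5 from B; exhaustive comparison says A
        assert assign_fixes_to_trees(fixes, trees, 5.0
                                     )["tree_id"].iloc[0] == "A"

    def test_exact_tie_breaks_to_smallest_id(self):
        trees = pd.DataFrame({"tree_id": ["B", "A"], "x": [-3.0, 3.0],
                              "y": [0.0, 0.0]})
        fixes = pd.DataFrame({"animal_id": "K1", "t": [T0],
                              "x": [0.0], "y": [0.0]})
        assert assign_fixes_to_trees(fixes, trees, 5.0
                                     )["tree_id"].iloc[0] == "A"

    def test_empty_tree_set_labels_none(self):
        fixes = pd.DataFrame({"animal_id": "K1", "t": [T0],
                              "x": [0.0], "y": [0.0]})
        out = assign_fixes_to_trees(fixes, pd.DataFrame(
            columns=["tree_id", "x", "y"]), 5.0)
        assert out["tree_id"].iloc[0] is None


class TestVisitMetrics:
    @staticmethod
    def _visits(rows, animal="K1", tree="A", day_frac=0.0):
        return pd.DataFrame([{
            "animal_id": animal, "tree_id": tree,
            "start_t": T0 + pd.Timedelta(hours=s),
            "end_t": T0 + pd.Timedelta(hours=e),
            "n_fixes": 2, "diel_fraction_day": day_frac,
        } for s, e in rows])

    def test_single_visit_rt_defined_ttor_undefined(self):
        met = visit_metrics(self._visits([(0, 8)]))
        row = met[met["period"] == "all"].iloc[0]
        assert row["n_visits"] == 1
        assert row["mean_rt_h"] == pytest.approx(8.0)
        assert math.isnan(row["mean_ttor_h"])

    def test_two_visits_mean_gap(self):
        met = visit_metrics(self._visits([(0, 8), (48, 56)]))
        row = met[met["period"] == "all"].iloc[0]
        assert row["n_visits"] == 2
        assert row["mean_rt_h"] == pytest.approx(8.0)
        assert row["mean_ttor_h"] == pytest.approx(40.0)

    def test_three_visits_average_of_gaps(self):
        met = visit_metrics(self._visits([(0, 4), (28, 32), (104, 108)]))
        row = met[met["period"] == "all"].iloc[0]
        assert row["mean_ttor_h"] == pytest.approx((24 + 72) / 2)

    def test_day_period_uses_majority_rule(self):
        vis = pd.concat([self._visits([(0, 8)], day_frac=0.8),
                         self._visits([(48, 56)], day_frac=0.2)])
        met = visit_metrics(vis).set_index("period")
        assert met.loc["day", "n_visits"] == 1
        assert met.loc["night", "n_visits"] == 1
        assert met.loc["all", "n_visits"] == 2

    def test_period_without_visits_has_nan_metrics(self):
        met = visit_metrics(self._visits([(0, 8)], day_frac=1.0))
        night = met[met["period"] == "night"].iloc[0]
        assert night["n_visits"] == 0
        assert math.isnan(night["mean_rt_h"])


class TestDielAndUtilities:
    @pytest.mark.parametrize("hour,expected", [
        (12, "day"), (3, "night"), (6, "day"), (18, "night"), (23, "night"),
    ])
    def test_diel_half_open_window(self, hour, expected):
        t = pd.Timestamp(f"2016-04-01 {hour:02d}:00").tz_localize(TZ)
        assert classify_diel(t, DAY_WINDOW) == expected

    def test_diel_rejects_naive_timestamp(self):
        with pytest.raises(ValueError, match="timezone|offset"):
            classify_diel(pd.Timestamp("2016-04-01 12:00"))

    def test_drms_examples(self):
        assert drms(np.array([[0.0, 0.0]] * 4), (0, 0)) == 0.0
        assert drms(np.array([[3.0, 0.0], [0.0, 4.0]]),
                    (0, 0)) == pytest.approx(math.sqrt(12.5))
        assert drms(np.array([[9.05, 0.0]]), (0, 0)) == pytest.approx(9.05)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_drms_translation_invariant(self, dx, dy):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 10, (20, 2))
        ref = np.array([1.0, -2.0])
        shifted = drms(pts + [dx, dy], tuple(ref + [dx, dy]))
        assert shifted == pytest.approx(drms(pts, tuple(ref)), rel=1e-9)

    @pytest.mark.parametrize("top,base,obs,expected", [
        (5.0, 4.0, 0.0, 3.0),
        (5.0, 4.0, 1.7, 4.7),
        (10.0, 0.0, 0.0, 10.0),
    ])
    def test_tree_height_right_triangle(self, top, base, obs, expected):
        assert tree_height(top, base, obs) == pytest.approx(expected)

    def test_tree_height_rejects_impossible_geometry(self):
        with pytest.raises(ValueError):
            tree_height(4.0, 5.0)

    def test_tracking_truncated_to_four_months(self):
        n = 1000
        fixes = pd.DataFrame({
            "animal_id": "K1",
            "t": [T0 + i * STEP for i in range(n)],
            "x": 0.0, "y": 0.0})
        out = truncate_tracking(fixes)
        span = out["t"].iloc[-1] - out["t"].iloc[0]
        assert span <= pd.Timedelta(days=120)
        assert len(out) == 120 * 6 + 1
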