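"""Class aggregation metrics against hand values and flood-fill oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treeuse.landscape import (aggregation_index, circular_window,
                               clumpiness, cohesion_index,
                               connectivity_table, pafrac, patch_components)
from conftest import grid


# ---------------------------------------------------------------------------
# oracles: BFS flood fill and explicit adjacency counting
# ---------------------------------------------------------------------------

def flood_fill_patches(vals, cls=1.0):
    """Independent 8-connected patch extraction by breadth-first search."""
    vals = np.asarray(vals, float)
    seen = np.zeros(vals.shape, bool)
    patches = []
    for r in range(vals.shape[0]):
        for c in range(vals.shape[1]):
            if vals[r, c] != cls or seen[r, c]:
                continue
            queue = [(r, c)]
            seen[r, c] = True
            cells = []
            while queue:
                rr, cc = queue.pop()
                cells.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < vals.shape[0]
                                and 0 <= nc < vals.shape[1]
                                and not seen[nr, nc]
                                and vals[nr, nc] == cls):
                            seen[nr, nc] = True
                            queue.append((nr, nc))
            perim = 0
            cellset = set(cells)
            for rr, cc in cells:
                for nr, nc in ((rr - 1, cc), (rr + 1, cc), (rr, cc - 1),
                               (rr, cc + 1)):
                    if (nr, nc) not in cellset:
                        perim += 1
            patches.append((len(cells), perim))
    return patches


def random_window(rng, shape=(12, 12), p=0.4):
    return grid((rng.random(shape) < p).astype(float))


class TestPatchComponents:
    def test_square_block(self):
        w = np.zeros((4, 4))
        w[1:3, 1:3] = 1
        _, areas, perims = patch_components(w)
        assert list(areas) == [4]
        assert list(perims) == [8]

    def test_diagonal_cells_are_one_patch(self):
        w = np.eye(2)
        _, areas, perims = patch_components(w)
        assert list(areas) == [2]
        assert list(perims) == [8]

    def test_checkerboard_is_single_patch(self):
        w = np.indices((4, 4)).sum(axis=0) % 2
        _, areas, _ = patch_components(w.astype(float))
        assert list(areas) == [8]

    def test_matches_flood_fill_oracle_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = random_window(rng)
            _, areas, perims = patch_components(w)
            got = sorted(zip(areas, perims))
            assert got == sorted(flood_fill_patches(w.values))


class TestAggregationIndex:
    def test_compact_block_is_100(self):
        w = np.zeros((10, 10))
        w[4:6, 4:6] = 1
        assert aggregation_index(w) == pytest.approx(100.0)

    def test_row_of_four_is_75(self):
        w = np.zeros((6, 6))
        w[2, 1:5] = 1
        assert aggregation_index(w) == pytest.approx(75.0)

    def test_single_cell_undefined(self):
        w = np.zeros((5, 5))
        w[2, 2] = 1
        assert math.isnan(aggregation_index(w))

    def test_range_and_translation_rotation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            w = random_window(rng, shape=(9, 9))
            ai = aggregation_index(w)
            if math.isnan(ai):
                continue
            assert 0.0 <= ai <= 100.0
            assert aggregation_index(np.rot90(w.values)) == pytest.approx(ai)
            padded = np.pad(w.values, 2)
            assert aggregation_index(padded) == pytest.approx(ai)


class TestCohesion:
    def test_block_in_hundred_cell_window(self):
        w = np.zeros((10, 10))
        w[0:2, 0:2] = 1
        expected = 100.0 * (1 - 8.0 / 16.0) / (1 - 0.1)
        assert cohesion_index(w) == pytest.approx(expected)
        assert expected == pytest.approx(55.5556, abs=1e-3)

    def test_all_singletons_is_zero(self):
        w = np.zeros((7, 7))
        w[::2, ::2] = 0  # keep empty
        w[1::3, 1::3] = 1
        _, areas, _ = patch_components(w)
        assert set(areas) == {1}
        assert cohesion_index(w) == pytest.approx(0.0)

    def test_bridging_two_patches_increases_cohesion(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            w = np.zeros((10, 10))
            w[2:5, 1:4] = 1
            w[2:5, 6:9] = 1
            before = cohesion_index(w)
            w[3, 4:6] = 1  # bridge
            after = cohesion_index(w)
            assert after > before

    def test_bounds_on_random_windows(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            w = random_window(rng)
            coh = cohesion_index(w)
            if not math.isnan(coh):
                assert 0.0 <= coh <= 100.0


class TestClumpy:
    def test_checkerboard_is_minus_one(self):
        w = np.indices((8, 8)).sum(axis=0) % 2
        assert clumpiness(w.astype(float)) == pytest.approx(-1.0)

    def test_compact_block_strongly_positive(self):
        w = np.zeros((20, 20))
        w[8:12, 8:12] = 1
        # hand count: like = 48/64 of class adjacencies, P = 0.04
        # -> (0.75 - 0.04) / (1 - 0.04)
        val = clumpiness(w)
        assert val == pytest.approx((0.75 - 0.04) / 0.96)
        assert val > 0.5

    def test_saturated_window_undefined(self):
        assert math.isnan(clumpiness(np.ones((5, 5))))
        assert math.isnan(clumpiness(np.zeros((5, 5))))

    def test_spatially_random_windows_center_near_zero(self):
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(500):
            w = (rng.random((20, 20)) < 0.5).astype(float)
            v = clumpiness(w)
            if not math.isnan(v):
                vals.append(v)
        assert abs(np.mean(vals)) < 0.05

    def test_bounds_on_random_windows(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            w = random_window(rng, p=0.3)
            v = clumpiness(w)
            if not math.isnan(v):
                assert -1.0 <= v <= 1.0


class TestPafrac:
    def test_squares_give_one(self):
        w = np.zeros((12, 12))
        w[0, 0] = 1                 # 1x1
        w[3:5, 3:5] = 1             # 2x2
        w[7:10, 7:10] = 1           # 3x3
        assert pafrac(w) == pytest.approx(1.0)

    def test_single_patch_undefined(self):
        w = np.zeros((5, 5))
        w[1:3, 1:3] = 1
        assert math.isnan(pafrac(w))

    def test_matches_independent_ols_on_random_windows(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(40):
            w = random_window(rng)
            val = pafrac(w)
            patches = flood_fill_patches(w.values)
            ln_p = np.log([p for _, p in patches])
            ln_a = np.log([a for a, _ in patches])
            if len(patches) < 2 or np.allclose(ln_p, ln_p[0]):
                assert math.isnan(val)
                continue
            slope = stats.linregress(ln_p, ln_a).slope
            assert val == pytest.approx(2.0 / slope, rel=1e-9)
            checked += 1
        assert checked > 10


class TestCircularWindow:
    def test_cell_count_matches_point_in_circle_enumeration(self):
        raster = grid(np.ones((40, 40)), cell_size=5.0)
        center = (100.0, 100.0)
        win = circular_window(raster, center, 50.0)
        count = 0
        for r in range(40):
            for c in range(40):
                x, y = raster.cell_center(r, c)
                if (x - 100) ** 2 + (y - 100) ** 2 <= 50.0 ** 2:
                    count += 1
        assert win.z == count
        assert not win.partial

    def test_tiny_radius_keeps_single_cell(self):
        raster = grid(np.ones((10, 10)), cell_size=5.0)
        win = circular_window(raster, (26.0, 26.0), 0.4)
        assert win.z == 1

    def test_corner_center_flags_partial(self):
        raster = grid(np.ones((10, 10)), cell_size=5.0)
        win = circular_window(raster, (2.0, 2.0), 20.0)
        assert win.partial

    def test_rejects_center_outside(self):
        raster = grid(np.ones((10, 10)), cell_size=5.0)
        with pytest.raises(ValueError):
            circular_window(raster, (1000.0, 0.0), 10.0)


class TestConnectivityTable:
    def test_unbroken_forest_buffer(self):
        raster = grid(np.ones((40, 40)), cell_size=5.0, role="habitat")
        trees = pd.DataFrame({"tree_id": ["T1"], "x": [100.0], "y": [100.0]})
        row = connectivity_table(raster, trees).iloc[0]
        assert row["woody_fraction"] == pytest.approx(1.0)
        # a fully woody *circular* window cannot quite reach the square-
        # packing maximum the index normalizes by
        assert row["ai"] == pytest.approx(100.0, abs=1.0)
        assert math.isnan(row["clumpy"])  # saturated class

    def test_cleared_buffer_metrics_missing_not_zero(self):
        raster = grid(np.zeros((40, 40)), cell_size=5.0, role="habitat")
        trees = pd.DataFrame({"tree_id": ["T1"], "x": [100.0], "y": [100.0]})
        row = connectivity_table(raster, trees).iloc[0]
        assert row["woody_fraction"] == 0.0
        for col in ("clumpy", "pafrac", "cohesion", "ai"):
            assert math.isnan(row[col])

    def test_mixed_buffer_agrees_with_per_metric_recomputation(self):
        rng = np.random.default_rng(29)
        vals = (rng.random((60, 60)) < 0.45).astype(float)
        raster = grid(vals, cell_size=5.0, role="habitat")
        trees = pd.DataFrame({"tree_id": ["T1", "T2"],
                              "x": [150.0, 160.0], "y": [150.0, 140.0]})
        table = connectivity_table(raster, trees).set_index("tree_id")
        for tid, (x, y) in {"T1": (150.0, 150.0),
                            "T2": (160.0, 140.0)}.items():
            win = circular_window(raster, (x, y), 50.0)
            assert table.loc[tid, "ai"] == pytest.approx(
                aggregation_index(win))
            assert table.loc[tid, "cohesion"] == pytest.approx(
                cohesion_index(win))
            assert table.loc[tid, "clumpy"] == pytest.approx(
                clumpiness(win))
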