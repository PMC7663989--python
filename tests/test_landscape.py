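"""Prediction maps, signatures, population arithmetic, fragmentation,
contrast tabulation."""

import numpy as np
import pandas as pd
import pytest

from chubsdm import (ClassRaster, aggregation_index, contrast_maps,
                     delineate_patches, fragmentation_metrics,
                     habitat_signature, max_like_adjacencies,
                     patch_diversity, population_estimate)
from chubsdm.grid import AlignmentError

# published prediction-map allocation: cells per class
TABLE_CELLS = {"Optimal": 58054, "Moderate": 240740,
               "Marginal": 167210, "Unsuitable": 95801}


def raster(classes, cell=90.0):
    classes = np.asarray(classes)
    return ClassRaster(classes, classes < 0, cell)


class TestPopulationEstimate:
    def test_published_population_table(self):
        out = population_estimate({3: 58054, 2: 240740, 1: 167210, 0: 95801})
        assert out.loc["Optimal", "max_population"] == pytest.approx(47_023_740)
        assert out.loc["Optimal", "min_population"] == pytest.approx(4_937_493, abs=1)
        assert out.loc["Moderate", "min_population"] == pytest.approx(2_924_991)
        assert out.loc["Moderate", "max_population"] == pytest.approx(19_499_940)
        assert out.loc["Marginal", "min_population"] == pytest.approx(1_354_401)
        assert out.loc["Total", "min_population"] == pytest.approx(9_216_885, abs=1)
        assert out.loc["Total", "max_population"] == pytest.approx(67_878_081)
        # areas follow the cell arithmetic (the printed 1,355 is a rounding)
        assert out.loc["Marginal", "area_km2"] == pytest.approx(1354.401)
        assert out.loc["Total", "cells"] == 561805

    def test_published_area_percentages(self):
        out = population_estimate({3: 58054, 2: 240740, 1: 167210, 0: 95801})
        assert out.loc["Optimal", "percent_area"] == pytest.approx(10.33, abs=0.5)
        assert out.loc["Moderate", "percent_area"] == pytest.approx(42.85, abs=0.5)
        assert out.loc["Marginal", "percent_area"] == pytest.approx(29.76, abs=0.5)
        assert out.loc["Unsuitable", "percent_area"] == pytest.approx(17.05, abs=0.5)

    def test_zero_cells(self):
        out = population_estimate({0: 0, 1: 0, 2: 0, 3: 0})
        assert out["min_population"].sum() == 0
        assert out["max_population"].sum() == 0

    def test_linearity_in_cell_counts(self):
        a = population_estimate({0: 10, 1: 20, 2: 30, 3: 40})
        b = population_estimate({0: 30, 1: 60, 2: 90, 3: 120})
        np.testing.assert_allclose(b["min_population"], 3 * a["min_population"])
        np.testing.assert_allclose(b["max_population"], 3 * a["max_population"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            population_estimate({0: -1, 1: 0, 2: 0, 3: 0})


class TestHabitatSignature:
    def test_zero_for_reference_like_class(self):
        feats = pd.DataFrame({"depth": [-5.0, -5.0, -1.0, -9.0]})
        sig = habitat_signature(feats, [2, 2, 0, 0])
        assert sig.loc["Moderate", "depth"] == pytest.approx(0.0)

    def test_one_sd_above(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 400)
        feats = pd.DataFrame({"v": base})
        sd = base.std(ddof=1)
        cls = (base > base.mean() + 0.5).astype(int) * 3
        sig = habitat_signature(feats, cls)
        shifted = base[cls == 3].mean() / sd
        assert sig.loc["Optimal", "v"] == pytest.approx(shifted, rel=0.05)

    def test_zero_reference_sd_flagged_nan(self):
        feats = pd.DataFrame({"v": [1.0, 1.0, 1.0], "w": [0.0, 1.0, 2.0]})
        sig = habitat_signature(feats, [0, 1, 1])
        assert np.isnan(sig.loc["Marginal", "v"])
        assert np.isfinite(sig.loc["Marginal", "w"])

    def test_grouped_classes(self):
        feats = pd.DataFrame({"v": [0.0, 10.0, 20.0, 30.0]})
        sig = habitat_signature(feats, [0, 1, 2, 3],
                                groups={"Appropriate": [2, 3]})
        expect = (25.0 - feats["v"].mean()) / feats["v"].std(ddof=1)
        assert sig.loc["Appropriate", "v"] == pytest.approx(expect)


class TestPatches:
    def test_single_block(self):
        r = raster([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        ps = delineate_patches(r)
        ones = ps.patches[ps.patches["class"] == 1]
        assert len(ones) == 1
        assert ones.iloc[0]["area_m2"] == pytest.approx(4 * 8100.0)

    def test_diagonal_connectivity(self):
        grid = [[1, 0], [0, 1]]
        assert len(delineate_patches(raster(grid), 8).patches
                   .query("`class` == 1")) == 1
        assert len(delineate_patches(raster(grid), 4).patches
                   .query("`class` == 1")) == 2

    def test_patch_count_vs_flood_fill(self):
        """Random 50x50 map: component counts match an independent
        flood-fill implementation."""
        rng = np.random.default_rng(7)
        grid = rng.integers(0, 4, (50, 50))
        ps = delineate_patches(raster(grid), connectivity=8)

        def flood_count(member):
            seen = np.zeros_like(member, dtype=bool)
            n = 0
            for i, j in np.argwhere(member):
                if seen[i, j]:
                    continue
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            u, v = a + da, b + db
                            if 0 <= u < 50 and 0 <= v < 50 \
                                    and member[u, v] and not seen[u, v]:
                                seen[u, v] = True
                                stack.append((u, v))
            return n

        for cls in range(4):
            expect = flood_count(grid == cls)
            got = len(ps.patches[ps.patches["class"] == cls])
            assert got == expect

    def test_patches_partition_class_cells(self):
        rng = np.random.default_rng(8)
        grid = rng.integers(0, 4, (30, 30))
        ps = delineate_patches(raster(grid))
        per_class = ps.patches.groupby("class")["cells"].sum()
        for cls in range(4):
            assert per_class[cls] == (grid == cls).sum()


class TestAggregationIndex:
    def test_square_block_is_100(self):
        r = raster([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        assert aggregation_index(r, 1) == pytest.approx(100.0)

    def test_plus_shape(self):
        # 5 cells in a plus: e = 4, max = 2*2*1 + 2*(5-4) - 1 = 5 -> 80%
        grid = [[-1, 2, -1], [2, 2, 2], [-1, 2, -1]]
        assert aggregation_index(raster(grid), 2) == pytest.approx(80.0)

    @pytest.mark.parametrize("n, expected", [
        (1, 0), (2, 1), (3, 2), (4, 4), (5, 5), (6, 7), (7, 8), (8, 10),
        (9, 12), (10, 13), (12, 17), (16, 24), (20, 31), (25, 40),
    ])
    def test_max_adjacency_construction(self, n, expected):
        """Largest-square construction against hand-enumerated values."""
        assert max_like_adjacencies(n) == expected

    def test_bounds_on_random_maps(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            grid = rng.integers(0, 3, (20, 20))
            r = raster(grid)
            for cls in range(3):
                if (grid == cls).sum() >= 2:
                    ai = aggregation_index(r, cls)
                    assert 0.0 <= ai <= 100.0


class TestFragmentationMetrics:
    def test_two_isolated_cells_distance(self):
        # same row, 3 cells apart: center distance 3 * 90, edge-to-edge 2 * 90
        grid = np.full((5, 7), 0)
        grid[2, 1] = 1
        grid[2, 4] = 1
        r = raster(grid)
        out = fragmentation_metrics(delineate_patches(r), r)
        assert out.loc["Marginal", "mean_nn_distance_m"] == pytest.approx(180.0)
        assert out.loc["Marginal", "n_patches"] == 2

    def test_single_patch_distance_undefined(self):
        grid = np.array([[1, 1], [0, 0]])
        r = raster(grid)
        out = fragmentation_metrics(delineate_patches(r), r)
        assert np.isnan(out.loc["Marginal", "mean_nn_distance_m"])

    def test_percent_areas_conserve(self):
        rng = np.random.default_rng(10)
        grid = rng.integers(0, 4, (40, 40))
        r = raster(grid)
        out = fragmentation_metrics(delineate_patches(r), r)
        assert out["percent_area"].sum() == pytest.approx(100.0)

    def test_mean_patch_size(self):
        grid = np.array([[1, 1, 0], [0, 0, 0], [1, 0, 0]])
        r = raster(grid, cell=100.0)
        out = fragmentation_metrics(delineate_patches(r), r)
        # patches of 2 and 1 cells at 10^4 m^2 each -> mean 1.5 ha
        assert out.loc["Marginal", "mean_patch_size_ha"] == pytest.approx(1.5)


class TestPatchDiversity:
    def test_published_diversity_values(self):
        """Shannon H over the two models' percent-area columns."""
        assert patch_diversity([10.2, 43.0, 29.8, 17.1]) == \
            pytest.approx(1.26, abs=0.005)
        assert patch_diversity([16.0, 36.2, 25.7, 22.1]) == \
            pytest.approx(1.34, abs=0.005)

    def test_equal_shares_maximal(self):
        assert patch_diversity([25, 25, 25, 25]) == pytest.approx(np.log(4))
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            assert patch_diversity(p) <= np.log(4) + 1e-12

    def test_single_class_zero(self):
        assert patch_diversity([100.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            patch_diversity([0.0, 0.0])


class TestContrastMaps:
    def test_identical_rasters(self):
        r = raster([[0, 1], [2, 3]])
        same, transitions, change = contrast_maps(r, r)
        assert same == 100.0
        assert transitions.empty
        assert (change == 0).all()

    def test_single_cell_change(self):
        a = raster([[0, 1], [2, 3]])
        b = raster([[3, 1], [2, 3]])
        same, transitions, change = contrast_maps(a, b)
        assert same == pytest.approx(75.0)
        assert len(transitions) == 1
        t = transitions.iloc[0]
        assert (t["from"], t["to"]) == ("Unsuitable", "Appropriate")
        assert t["area_km2"] == pytest.approx(8100 / 1e6)
        assert change[0, 0] == 3

    def test_transition_areas_vs_crosstab(self):
        rng = np.random.default_rng(12)
        a = raster(rng.integers(0, 4, (25, 25)))
        b = raster(rng.integers(0, 4, (25, 25)))
        same, transitions, _ = contrast_maps(a, b, group_appropriate=False)
        # brute-force cross-tabulation oracle
        labels = ["Unsuitable", "Marginal", "Moderate", "Optimal"]
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                cells = int(((a.classes == i) & (b.classes == j)).sum())
                row = transitions[(transitions["from"] == labels[i])
                                  & (transitions["to"] == labels[j])]
                got = 0 if row.empty else row.iloc[0]["cells"]
                assert got == cells
        agree = float((a.classes == b.classes).mean()) * 100
        assert same == pytest.approx(agree)

    def test_area_conservation(self):
        rng = np.random.default_rng(13)
        a = raster(rng.integers(0, 4, (20, 20)))
        b = raster(rng.integers(0, 4, (20, 20)))
        same, transitions, _ = contrast_maps(a, b)
        assert same + transitions["percent_area"].sum() == pytest.approx(100.0)

    def test_misaligned_rejected(self):
        with pytest.raises(AlignmentError):
            contrast_maps(raster([[0, 1]]), raster([[0], [1]]))
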