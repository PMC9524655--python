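"""LISA cluster detection, square fitting, TOPSIS, conflict counting."""

import numpy as np
import pandas as pd
import pytest

from seaplan.grid import PlanningGrid, ScoredLayer
from seaplan.siting import (
    ConflictReport,
    SitingOption,
    attach_criteria,
    conflict_matrix,
    count_conflicts,
    fit_square_options,
    local_morans,
    select_final_options,
    significant_clusters,
    square_side,
    topsis_closeness,
    topsis_rank,
)


def surface_with_block(n=5, lo=0.2, hi=0.9, block=slice(1, 4)):
    vals = np.full((n, n), lo)
    vals[block, block] = hi
    return vals


class TestLocalMorans:
    def test_planted_block_is_significant_hh(self):
        grid = PlanningGrid(n_rows=5, n_cols=5)
        lisa = local_morans(surface_with_block(), grid=grid,
                            permutations=999, seed=42)
        # the interior of the 3x3 high block clusters with itself
        assert lisa.quadrant[2, 2] == 1
        assert lisa.p_value[2, 2] <= 0.05

    def test_local_statistic_matches_double_loop(self, rng):
        """I_i agrees with an explicit neighbor double loop."""
        grid = PlanningGrid(n_rows=7, n_cols=7)
        vals = rng.uniform(0, 1, grid.shape)
        lisa = local_morans(vals, grid=grid, permutations=9, seed=0)
        z = vals - vals.mean()
        for r in (0, 3, 6):
            for c in (0, 2, 5):
                nbrs = [
                    z[rr, cc]
                    for rr in range(max(0, r - 1), min(7, r + 2))
                    for cc in range(max(0, c - 1), min(7, c + 2))
                    if (rr, cc) != (r, c)
                ]
                expected = z[r, c] * np.mean(nbrs)
                assert lisa.local_i[r, c] == pytest.approx(expected, abs=1e-12)

    def test_anselin_sum_identity(self, rng):
        """sum(I_i) / sum(z_i^2) equals global Moran's I within 1e-9."""
        grid = PlanningGrid(n_rows=12, n_cols=12)
        vals = rng.uniform(0, 1, grid.shape)
        lisa = local_morans(vals, grid=grid, permutations=9, seed=0)
        z = (vals - vals.mean()).ravel()
        # independent global Moran's I with row-standardized queen weights
        n = z.size
        num = 0.0
        for r in range(12):
            for c in range(12):
                nbrs = [
                    (rr, cc)
                    for rr in range(max(0, r - 1), min(12, r + 2))
                    for cc in range(max(0, c - 1), min(12, c + 2))
                    if (rr, cc) != (r, c)
                ]
                w = 1.0 / len(nbrs)
                num += z[r * 12 + c] * sum(w * z[rr * 12 + cc]
                                           for rr, cc in nbrs)
        global_i = num / np.sum(z**2)
        assert lisa.global_moran() == pytest.approx(global_i, abs=1e-9)
        assert np.nansum(lisa.local_i) / np.sum(z**2) == \
            pytest.approx(global_i, abs=1e-9)

    def test_checkerboard_negative_autocorrelation(self):
        """Under rook contiguity every neighbor of a checkerboard cell
        has the opposite value, so every local statistic is negative."""
        grid = PlanningGrid(n_rows=6, n_cols=6)
        vals = (np.indices((6, 6)).sum(axis=0) % 2).astype(float) * 0.5 + 0.25
        lisa = local_morans(vals, grid=grid, scheme="rook",
                            permutations=9, seed=0)
        assert np.all(lisa.local_i[lisa.analysis_mask] < 0)

    def test_constant_surface_errors(self, grid10):
        with pytest.raises(ValueError, match="constant"):
            local_morans(np.full(grid10.shape, 0.5), grid=grid10,
                         permutations=9, seed=0)

    def test_permutation_determinism(self, rng):
        grid = PlanningGrid(n_rows=8, n_cols=8)
        vals = rng.uniform(0, 1, grid.shape)
        a = local_morans(vals, grid=grid, permutations=99, seed=7)
        b = local_morans(vals, grid=grid, permutations=99, seed=7)
        np.testing.assert_array_equal(a.p_value, b.p_value)

    def test_isolated_cells_warn_and_drop(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[:4, :4] = True
        mask[6, 6] = True  # isolated from the block
        grid = PlanningGrid(n_rows=7, n_cols=7, study_mask=mask)
        vals = np.where(mask, np.arange(49, dtype=float).reshape(7, 7) / 49,
                        np.nan)
        vals[vals == 0] = 0.01
        with pytest.warns(UserWarning, match="isolated"):
            lisa = local_morans(vals, grid=grid, permutations=9, seed=0)
        assert np.isnan(lisa.local_i[6, 6])


class TestSignificantClusters:
    def test_no_significant_cells_empty(self, rng):
        grid = PlanningGrid(n_rows=10, n_cols=10)
        # i.i.d. noise: expect no (or almost no) HH cells; force empty by
        # alpha = 0
        vals = rng.uniform(0, 1, grid.shape)
        lisa = local_morans(vals, grid=grid, permutations=99, seed=1)
        labels = significant_clusters(lisa, alpha=1e-9)
        assert labels.max() == 0

    def test_single_block_single_cluster(self):
        grid = PlanningGrid(n_rows=5, n_cols=5)
        lisa = local_morans(surface_with_block(), grid=grid,
                            permutations=999, seed=42)
        labels = significant_clusters(lisa)
        assert labels.max() == 1

    def test_two_disjoint_blocks_two_clusters(self):
        vals = np.full((9, 20), 0.2)
        vals[3:6, 2:5] = 0.9
        vals[3:6, 14:17] = 0.9
        grid = PlanningGrid(n_rows=9, n_cols=20)
        lisa = local_morans(vals, grid=grid, permutations=999, seed=42)
        labels = significant_clusters(lisa)
        assert labels.max() == 2


class TestFitSquares:
    def make_cluster(self, shape, block_rows, block_cols):
        m = np.zeros(shape, dtype=int)
        m[block_rows, block_cols] = 1
        return m

    def grid(self, shape):
        return PlanningGrid(n_rows=shape[0], n_cols=shape[1],
                            cell_area_ac=10.0)

    def test_side_lengths(self):
        assert square_side(2000, 10) == 14
        assert square_side(1500, 10) == 12
        assert square_side(1000, 10) == 10
        assert square_side(500, 10) == 7

    def test_7x7_cluster_one_500ac_option(self):
        m = self.make_cluster((10, 10), slice(1, 8), slice(1, 8))
        opts = fit_square_options(m, 1, self.grid((10, 10)))
        assert len(opts) == 1
        assert opts[0].size_class_ac == 500 and opts[0].side == 7

    def test_6x20_cluster_no_options(self):
        m = self.make_cluster((8, 22), slice(1, 7), slice(1, 21))
        assert fit_square_options(m, 1, self.grid((8, 22))) == []

    def test_20x20_cluster_all_sizes(self):
        m = self.make_cluster((22, 22), slice(1, 21), slice(1, 21))
        opts = fit_square_options(m, 1, self.grid((22, 22)))
        sizes = {o.size_class_ac for o in opts}
        assert sizes == {2000, 1500, 1000, 500}
        assert any(o.side == 14 for o in opts)

    def test_enumeration_matches_brute_force(self, rng):
        """Block counts agree with a naive all-positions scan."""
        m = (rng.uniform(0, 1, (15, 15)) > 0.3).astype(int)
        g = self.grid((15, 15))
        opts = fit_square_options(m, 1, g, sizes_ac=[500])
        s = square_side(500, 10)
        brute = sum(
            np.all(m[r:r + s, c:c + s] == 1)
            for r in range(15 - s + 1) for c in range(15 - s + 1)
        )
        assert len(opts) == brute


class TestTopsis:
    def test_ideal_option_ranks_first(self):
        m = np.array([[1.0, 5.0], [2.0, 7.0], [1.0, 5.0]])
        c = topsis_closeness(m, benefit_flags=[False, False])
        assert c[0] == pytest.approx(1.0)
        assert c[0] == c[2]  # duplicates of the ideal tie

    def test_dominance_on_random_matrices(self, rng):
        """An option at most as costly as another on every criterion
        never ranks below it (1,000 random 5-option matrices)."""
        violations = 0
        for _ in range(1000):
            m = rng.uniform(0.1, 10.0, size=(5, 3))
            m[1] = m[0] * rng.uniform(1.01, 2.0, size=3)  # 1 dominated by 0
            c = topsis_closeness(m, benefit_flags=[False] * 3)
            if c[0] < c[1] - 1e-12:
                violations += 1
        assert violations == 0

    def test_closeness_in_unit_interval(self, rng):
        for _ in range(50):
            m = rng.uniform(0, 100, size=(rng.integers(2, 8), 4))
            c = topsis_closeness(m, benefit_flags=[True, False, True, False])
            assert np.all((c >= 0) & (c <= 1))

    def test_hand_computed_two_by_three(self):
        """Frozen from an independent step-by-step evaluation of the
        normalize/weight/distance recipe."""
        m = np.array([[10.0, 0.2, 0.5], [20.0, 0.1, 0.8]])
        c = topsis_closeness(m, benefit_flags=[False, False, False])
        assert c[0] == pytest.approx(0.550974, abs=1e-5)
        assert c[1] == pytest.approx(0.449026, abs=1e-5)

    def test_scale_invariance(self, rng):
        m = rng.uniform(1, 10, size=(6, 3))
        c1 = topsis_closeness(m, benefit_flags=[False, True, False])
        m2 = m * np.array([100.0, 0.01, 7.5])
        c2 = topsis_closeness(m2, benefit_flags=[False, True, False])
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_single_option_convention(self):
        with pytest.warns(UserWarning, match="single"):
            c = topsis_closeness(np.array([[1.0, 2.0]]), [False, False])
        assert c[0] == 1.0


def make_option(sub, cid, r, c, side=7, **crit):
    o = SitingOption(subregion=sub, cluster_id=cid, row0=r, col0=c,
                     side=side, size_class_ac=500)
    o.criteria = crit
    return o


class TestSelection:
    def test_top_three_selected(self):
        opts = [make_option("West", 1, i, 0) for i in range(5)]
        for k, o in enumerate(opts, 1):
            o.final_rank = k
        out = select_final_options(opts, per_subregion=3)
        assert [o.final_rank for o in out] == [1, 2, 3]
        assert [o.option_id for o in out] == ["W-1", "W-2", "W-3"]

    def test_empty_subregion_stays_empty(self):
        assert select_final_options([], per_subregion=3) == []

    def test_two_available_returns_both_with_warning(self):
        opts = [make_option("East", 1, i, 0) for i in range(2)]
        for k, o in enumerate(opts, 1):
            o.final_rank = k
        with pytest.warns(UserWarning, match="only 2"):
            out = select_final_options(opts, per_subregion=3)
        assert len(out) == 2


class TestConflicts:
    def test_planted_overlaps_match_brute_force(self, rng):
        grid = PlanningGrid(n_rows=20, n_cols=20)
        layers = []
        for k in range(4):
            vals = np.ones(grid.shape)
            mask = rng.uniform(0, 1, grid.shape) < 0.3
            vals[mask] = 0.2
            layers.append(ScoredLayer(grid, vals, name=f"sp{k}"))
        opts = []
        for j, (r, c) in enumerate([(2, 2), (10, 11), (0, 13)]):
            o = make_option("West", 1, r, c, side=5)
            o.option_id = f"W-{j + 1}"
            opts.append(o)
        report = conflict_matrix(opts, layers)
        assert report.total_pairs == 12
        for lyr in layers:
            for o in opts:
                fp = o.footprint(grid.shape)
                expected = "Yes" if (lyr.values[fp] < 1).any() else "No"
                assert report.table.loc[lyr.name, o.option_id] == expected

    def test_option_outside_all_footprints(self, grid10):
        vals = np.ones(grid10.shape)
        vals[8:, 8:] = 0.1
        layers = [ScoredLayer(grid10, vals, name="sp")]
        o = make_option("West", 1, 0, 0, side=3)
        o.option_id = "W-1"
        report = conflict_matrix([o], layers)
        assert (report.table == "No").all().all()
        assert report.n_conflicts == 0

    def test_count_conflicts_on_reference_table(self):
        """The shipped nine-option example table: 108 pairs, 10
        conflicts, 3 conflicts excluding the widely distributed ray."""
        from importlib import resources

        with resources.files("seaplan.data").joinpath(
            "gulf_aoa_conflicts.csv"
        ).open() as fh:
            table = pd.read_csv(fh, index_col=0)
        counts = count_conflicts(
            table, exclude=["Giant manta ray upper modeled distribution"]
        )
        assert counts["total_pairs"] == 108
        assert counts["n_conflicts"] == 10
        assert counts["n_conflicts_excluding"] == 3
        assert counts["conflict_pct"] == pytest.approx(100 * 10 / 108)


def test_attach_criteria_distances(grid10):
    o = make_option("West", 1, 2, 2, side=4)
    fishing = np.full(grid10.shape, 0.5)
    vessel = np.full(grid10.shape, 0.25)
    cx, cy = o.centroid(grid10)
    inlets = np.array([[cx, cy + 5000.0], [cx + 50_000.0, cy]])
    attach_criteria([o], grid10, inlets, fishing, vessel)
    assert o.criteria["distance_to_inlet"] == pytest.approx(5.0)
    assert o.criteria["fishing_effort"] == 0.5
    assert o.criteria["vessel_traffic"] == 0.25
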