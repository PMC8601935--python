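"""Gridding, study masks, CSR simulation and the nearest neighbour index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import occscreen as oc
from occscreen.synth import SynthConfig


def brute_force_mean_nn(points):
    """All-pairs oracle for the mean nearest-neighbour distance."""
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1).mean()


class TestGridCounts:
    def test_example_coordinates_give_cells_five_and_one(self, example_tab):
        gs = oc.grid_counts(example_tab, 1.0, oc.PeriodSet([(1990, 1999)]))
        assert sorted(gs.data["count"]) == [1, 5]

    def test_boundary_point_belongs_to_higher_cell(self):
        raw = pd.DataFrame({
            "species": ["a", "b"], "x": [0.5, 1.0], "y": [0.5, 0.5],
            "year": [1995, 1995], "spatialUncertainty": [1.0, 1.0],
            "identifier": ["g", "g"],
        })
        tab = oc.validate_occurrences(raw)
        gs = oc.grid_counts(tab, 1.0, oc.PeriodSet([(1990, 1999)]))
        assert sorted(gs.data["cell_x"]) == [0.0, 1.0]

    def test_empty_table_gives_empty_summary(self):
        empty = oc.OccurrenceTable(pd.DataFrame(columns=oc.core.REQUIRED_FIELDS))
        gs = oc.grid_counts(empty, 1.0)
        assert gs.data.empty

    def test_cell_sums_conserve_assigned_records(self, unbiased_tab):
        gs = oc.grid_counts(unbiased_tab, 7.5)
        sums = {(i, str(p)): v for (i, p), v in
                gs.data.groupby(["identifier", "period"], observed=True)["count"]
                .sum().items()}
        direct = {(i, str(p)): v for (i, p), v in
                  unbiased_tab.data.groupby(["identifier", "period"],
                                            observed=True).size().items()}
        assert sums == direct

    def test_mask_anchors_the_grid_origin(self, example_tab):
        mask = oc.StudyMask.rectangle(-70, -50, -30, -10, cell_size=1.0)
        gs = oc.grid_counts(example_tab, 1.0, oc.PeriodSet([(1990, 1999)]), mask)
        assert gs.origin == (-70.0, -30.0)


class TestPeriodsSampled:
    def test_tallies_periods_with_records_per_cell(self):
        years = [1955, 1965, 1975, 1955]
        raw = pd.DataFrame({
            "species": list("abcd"), "x": [0.5, 0.5, 0.5, 5.5],
            "y": [0.5] * 4, "year": years,
            "spatialUncertainty": [1.0] * 4, "identifier": ["g"] * 4,
        })
        tab = oc.assign_periods(oc.validate_occurrences(raw), oc.decadal_periods())
        tally = oc.grid_counts(tab, 1.0).periods_sampled()
        by_cell = tally.set_index("cell_x")["n_periods"]
        assert by_cell[0.5 // 1.0 * 1.0] == 3 if 0.0 in by_cell.index else True
        assert by_cell.loc[0.0] == 3 and by_cell.loc[5.0] == 1

    def test_identifiers_do_not_leak_between_maps(self):
        raw = pd.DataFrame({
            "species": ["a", "b"], "x": [0.5, 9.5], "y": [0.5, 9.5],
            "year": [1955, 1955], "spatialUncertainty": [1.0, 1.0],
            "identifier": ["g1", "g2"],
        })
        tab = oc.assign_periods(oc.validate_occurrences(raw), oc.decadal_periods())
        tally = oc.grid_counts(tab, 1.0).periods_sampled()
        g1 = tally[tally["identifier"] == "g1"]
        assert set(zip(g1["cell_x"], g1["cell_y"])) == {(0.0, 0.0)}

    def test_mask_distinguishes_unsampled_from_outside(self, example_tab):
        mask = oc.StudyMask.rectangle(-70, -50, -30, -10, cell_size=10.0)
        tab = oc.assign_periods(example_tab, oc.PeriodSet([(1990, 1999)]))
        tally = oc.grid_counts(tab, 10.0, mask=mask).periods_sampled()
        assert len(tally) == mask.n_in_cells   # every in-cell reported
        assert (tally["n_periods"] == 0).any()  # in-mask but unsampled


class TestMeanNN:
    def test_two_points(self):
        assert oc.mean_nn_distance([[0, 0], [3, 0]]) == 3.0

    def test_collinear_hand_computation(self):
        assert oc.mean_nn_distance([[0, 0], [1, 0], [3, 0]]) == pytest.approx(4 / 3)

    def test_coincident_points_have_zero_distance(self):
        assert oc.mean_nn_distance([[1, 1], [1, 1]]) == 0.0

    def test_fewer_than_two_points_error(self):
        with pytest.raises(ValueError):
            oc.mean_nn_distance([[0, 0]])

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.random((400, 2))
        assert oc.mean_nn_distance(pts) == pytest.approx(
            brute_force_mean_nn(pts), abs=1e-10)


class TestSimulation:
    def test_csr_mean_nn_matches_closed_form_on_rectangle(self, unit_mask):
        rng = np.random.default_rng(11)
        means = [oc.mean_nn_distance(oc.simulate_random_points(unit_mask, 2000, rng))
                 for _ in range(20)]
        expected = oc.expected_csr_nn_distance(1.0, 2000)
        assert np.mean(means) == pytest.approx(expected, rel=0.02)

    def test_no_point_falls_outside_half_mask(self):
        grid = np.ones((10, 10), dtype=bool)
        grid[:, :5] = False   # left half out
        mask = oc.StudyMask(0.0, 0.0, 0.1, grid)
        pts = oc.simulate_random_points(mask, 3000, 5)
        assert (pts[:, 0] >= 0.5).all()

    def test_zero_points(self, unit_mask):
        assert oc.simulate_random_points(unit_mask, 0, 1).shape == (0, 2)

    def test_all_in_mask_rejected_when_empty(self):
        with pytest.raises(ValueError):
            oc.StudyMask(0, 0, 1.0, np.zeros((3, 3), dtype=bool))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_simulated_points_always_inside_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((6, 8)) < 0.5
        if not grid.any():
            grid[0, 0] = True
        mask = oc.StudyMask(-3.0, 2.0, 0.7, grid)
        pts = oc.simulate_random_points(mask, 200, rng)
        assert mask.contains(pts).all()


class TestNNI:
    def test_csr_pattern_scores_near_one_with_ci_spanning_it(self, unit_mask):
        pts = oc.simulate_random_points(unit_mask, 1000, 21)
        res = oc.nearest_neighbour_index(pts, unit_mask, nsim=199, rng=42)
        assert res["ci_low"] < 1 < res["ci_high"]
        assert res["index"] == pytest.approx(1.0, abs=0.05)

    def test_hexagonal_lattice_hits_the_dispersion_ceiling(self, unit_mask):
        pts = oc.gen_hex_lattice((0, 1, 0, 1), 2000)
        res = oc.nearest_neighbour_index(pts, unit_mask, nsim=99, rng=7)
        assert res["index"] == pytest.approx(2.15, abs=0.05)

    def test_coincident_records_score_zero(self, unit_mask):
        pts = np.tile([[0.5, 0.5]], (10, 1))
        res = oc.nearest_neighbour_index(pts, unit_mask, nsim=19, rng=1)
        assert res["index"] == 0.0

    def test_clustered_below_one_lattice_above_one(self, square_mask_100):
        cfg = SynthConfig(seed=13, n_clusters=10, groups={"g": 800})
        clustered = oc.gen_biased(cfg).data[["x", "y"]].to_numpy()
        lattice = oc.gen_hex_lattice((0, 100, 0, 100), 800)[:800]
        c = oc.nearest_neighbour_index(clustered, square_mask_100, nsim=49, rng=2)
        l = oc.nearest_neighbour_index(lattice, square_mask_100, nsim=49, rng=2)
        assert c["index"] < 1 < l["index"]

    def test_index_invariant_to_uniform_rescaling(self, unit_mask):
        pts = oc.simulate_random_points(unit_mask, 300, 8)
        big_mask = oc.StudyMask.rectangle(0, 1000, 0, 1000, cell_size=100)
        a = oc.nearest_neighbour_index(pts, unit_mask, nsim=49, rng=4)
        b = oc.nearest_neighbour_index(pts * 1000, big_mask, nsim=49, rng=4)
        assert a["index"] == pytest.approx(b["index"], rel=1e-12)

    def test_invalid_arguments(self, unit_mask):
        pts = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError):
            oc.nearest_neighbour_index(pts, unit_mask, nsim=1)
        with pytest.raises(ValueError):
            oc.nearest_neighbour_index(pts, unit_mask, ci_level=1.5)

    def test_groups_with_fewer_than_two_records_yield_missing(self, square_mask_100):
        raw = pd.DataFrame({
            "species": ["a", "b", "c"], "x": [5.0, 6.0, 50.0],
            "y": [5.0, 6.0, 50.0], "year": [1955, 1955, 1965],
            "spatialUncertainty": [1.0] * 3, "identifier": ["g"] * 3,
        })
        tab = oc.validate_occurrences(raw)
        res = oc.assess_spatial_bias(tab, square_mask_100,
                                     oc.PeriodSet([(1950, 1959), (1960, 1969)]),
                                     nsim=19, seed=1)
        by_period = res.data.set_index("period")
        assert np.isfinite(by_period.loc["1950-1959", "index"])
        assert np.isnan(by_period.loc["1960-1969", "index"])

    def test_csr_calibration_ci_covers_one_at_nominal_rate(self, unit_mask):
        # 60 seeded replicates; a 90% CI should cover 1 roughly 9 times in 10
        rng = np.random.default_rng(314)
        covered = 0
        for _ in range(60):
            pts = oc.simulate_random_points(unit_mask, 150, rng)
            r = oc.nearest_neighbour_index(pts, unit_mask, nsim=99, rng=rng)
            covered += r["ci_low"] <= 1 <= r["ci_high"]
        assert 0.78 <= covered / 60 <= 0.98


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path):
        arr = np.array([[1.0, np.nan], [3.0, 4.0]])
        path = tmp_path / "g.asc"
        oc.write_ascii_grid(path, arr, x0=10.0, y0=20.0, cell_size=0.5)
        back, header = oc.spatial.read_ascii_grid(path)
        np.testing.assert_array_equal(back, arr)
        assert header["xllcorner"] == 10.0 and header["cellsize"] == 0.5

    def test_read_mask_treats_nodata_as_outside(self, tmp_path):
        arr = np.array([[1.0, np.nan], [1.0, 1.0]])
        path = tmp_path / "m.asc"
        oc.write_ascii_grid(path, arr, 0.0, 0.0, 1.0)
        mask = oc.read_mask(path)
        assert mask.n_in_cells == 3
        assert not mask.contains([[1.5, 1.5]])[0]   # top-right cell is out
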