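import itertools

import numpy as np
import pytest

from wildens import costs, effort, removal


def brute_force_subgrids(rows, cols, min_cameras, exclude_full):
    """Independent rectangle scan: every distinct contiguous cell block."""
    out = set()
    for r0, r1 in itertools.combinations(range(rows + 1), 2):
        for c0, c1 in itertools.combinations(range(cols + 1), 2):
            h, w = r1 - r0, c1 - c0
            if h * w < min_cameras:
                continue
            if exclude_full and h == rows and w == cols:
                continue
            out.add((r0, c0, h, w))
    return out


class TestSubgridEnumeration:
    def test_study_grid_yields_47(self):
        assert len(effort.enumerate_camera_subgrids(4, 5, 6, True)) == 47

    def test_two_by_two_yields_eight(self):
        assert len(effort.enumerate_camera_subgrids(2, 2, 1, True)) == 8

    def test_floor_above_grid_size_empty(self):
        assert effort.enumerate_camera_subgrids(4, 5, 20, True) == []

    def test_matches_brute_force_on_all_small_grids(self):
        for rows in range(1, 6):
            for cols in range(1, 6):
                for floor in range(1, rows * cols + 2):
                    for excl in (True, False):
                        got = set(effort.enumerate_camera_subgrids(rows, cols, floor, excl))
                        assert got == brute_force_subgrids(rows, cols, floor, excl)


class TestScaledBias:
    @pytest.mark.parametrize(
        "reduced,full,expected",
        [(2.0, 2.0, 0.0), (2.02, 2.00, 0.01), (1.98, 2.00, -0.01)],
    )
    def test_values(self, reduced, full, expected):
        assert effort.scaled_bias(reduced, full) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            effort.scaled_bias(1.0, 0.0)


class TestReduceFecal:
    def test_full_effort_bias_exactly_zero(self, fecal_detections):
        cell = effort.reduce_fecal(fecal_detections, 4, 6, n_boot=5, seed=0)
        assert cell.scaled_bias == 0.0
        assert cell.prop_converged == 1.0
        assert cell.cost_usd == pytest.approx(11355.0)

    def test_minimal_effort_more_biased_than_full(self, fecal_detections):
        cell = effort.reduce_fecal(fecal_detections, 1, 2, n_boot=20, seed=0)
        assert cell.abs_scaled_bias > 0.0
        assert cell.cost_usd == pytest.approx(6385.0)

    def test_zero_bootstrap_rejected(self, fecal_detections):
        with pytest.raises(ValueError):
            effort.reduce_fecal(fecal_detections, 2, 3, n_boot=0)

    def test_seed_reproducibility(self, fecal_detections):
        a = effort.reduce_fecal(fecal_detections, 2, 4, n_boot=10, seed=42)
        b = effort.reduce_fecal(fecal_detections, 2, 4, n_boot=10, seed=42)
        assert a.scaled_bias == b.scaled_bias
        assert a.variance == b.variance


class TestReduceCamera:
    def test_full_design_deterministic_zero_bias(self, camera_dataset):
        _, _, cam = camera_dataset
        cell = effort.reduce_camera([cam], (0, 0, 4, 5), 12, n_boot=7, seed=0)
        assert cell.scaled_bias == 0.0
        assert cell.n_replicates == 1  # unique full window
        assert cell.prop_converged == 1.0

    def test_small_subgrid_biased_or_failing(self, camera_dataset):
        _, _, cam = camera_dataset
        cell = effort.reduce_camera([cam], (0, 0, 2, 3), 6, n_boot=6, seed=1)
        assert cell.effort.n_units == 6
        # either bias appears or sufficiency failures are recorded
        assert cell.prop_converged < 1.0 or cell.abs_scaled_bias > 0.0


class TestRemovalSimulation:
    def test_zero_capture_rate_removes_nothing(self):
        _, series = effort.simulate_removal_landscape(
            theta_given_encounter=0.0, seed=0
        )
        assert series.total_removed == 0

    def test_removals_bounded_by_population(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            truth, series = effort.simulate_removal_landscape(
                theta_given_encounter=0.3, rng=rng
            )
            assert series.total_removed <= truth.n_animals

    def test_animals_beyond_truncation_radius_never_captured(self):
        # one animal far from the single trap
        centroids = np.array([[0.5, 0.5]])
        truth, series = effort.simulate_removal_landscape(
            extent_km=(9.0, 6.0),
            n_traps=1,
            n_nights=200,
            theta_given_encounter=1.0,
            centroids=centroids,
            seed=0,
        )
        # trap block is centred: trap within (4..5, 2.5..3.5); animal > 3 sigma away
        assert series.total_removed == 0

    def test_expected_catch_declines_under_constant_effort(self):
        rng = np.random.default_rng(3)
        early, late = 0, 0
        for _ in range(60):
            _, series = effort.simulate_removal_landscape(n_nights=14, rng=rng)
            early += series.removals[:7].sum()
            late += series.removals[7:].sum()
        assert early > late

    def test_seed_determinism(self):
        t1, s1 = effort.simulate_removal_landscape(seed=9)
        t2, s2 = effort.simulate_removal_landscape(seed=9)
        assert np.array_equal(s1.removals, s2.removals)
        assert np.array_equal(t1.centroids, t2.centroids)

    def test_calibrated_catch_matches_field_scale(self):
        """~20 removals per site (10 traps, 14 nights) at default settings."""
        rng = np.random.default_rng(42)
        totals = [
            effort.simulate_removal_landscape(rng=rng)[1].total_removed
            for _ in range(200)
        ]
        assert 15.0 <= np.mean(totals) <= 25.0


class TestAreaRegression:
    def test_identical_areas_give_flat_plane(self):
        records = [
            {"N_hat": 25.0 * d, "true_density": d, "n_traps": R, "n_days": D}
            for d, R, D in [(2.0, 2, 4), (2.5, 5, 10), (3.0, 8, 16), (2.2, 10, 4)]
        ]
        am = effort.effective_area_regression(records)
        assert am.intercept == pytest.approx(25.0, abs=1e-8)
        assert am.coef_days == pytest.approx(0.0, abs=1e-8)
        assert am.coef_traps == pytest.approx(0.0, abs=1e-8)
        assert am.predict(3, 12) == pytest.approx(25.0)

    def test_ols_recovery_of_linear_surface(self):
        rng = np.random.default_rng(0)
        records = []
        for _ in range(60):
            R = rng.integers(1, 11)
            D = rng.integers(4, 21)
            area = 5 + 0.2 * D + 1.1 * R + rng.normal(0, 0.1)
            records.append(
                {"N_hat": area * 2.5, "true_density": 2.5, "n_traps": R, "n_days": D}
            )
        am = effort.effective_area_regression(records)
        assert abs(am.intercept - 5.0) < 3 * am.resid_se
        assert abs(am.coef_days - 0.2) < 3 * am.resid_se
        assert abs(am.coef_traps - 1.1) < 3 * am.resid_se

    def test_too_few_design_points_rejected(self):
        records = [
            {"N_hat": 10.0, "true_density": 2.0, "n_traps": 2, "n_days": 4},
            {"N_hat": 20.0, "true_density": 2.0, "n_traps": 5, "n_days": 10},
        ]
        with pytest.raises(ValueError):
            effort.effective_area_regression(records)

    def test_collinear_design_rejected(self):
        # traps always equal to days: effects inseparable
        records = [
            {"N_hat": 10.0 * k, "true_density": 2.0, "n_traps": k, "n_days": k}
            for k in (2, 4, 6, 8)
        ]
        with pytest.raises(ValueError):
            effort.effective_area_regression(records)


class TestRemovalSurface:
    def test_zero_sims_rejected(self):
        with pytest.raises(ValueError):
            effort.removal_bias_surface(n_sims=0)

    def test_costs_span_printed_range(self):
        am = effort.AreaModel(5.0, 0.5, 1.5, 0.9, 1.0, min_area_km2=1.0)
        cells = effort.removal_bias_surface(
            trap_grid=(1, 10), day_grid=(4, 20), n_sims=2, seed=0, area_model=am
        )
        cost = {(c.effort.n_units, c.effort.n_days): c.cost_usd for c in cells}
        assert cost[(1, 4)] == pytest.approx(2947.0)
        assert cost[(10, 20)] == pytest.approx(11795.0)

    def test_information_rich_cell_less_biased(self):
        am = effort.fit_area_model(
            trap_grid=(1, 4, 10), day_grid=(4, 12, 20), n_sims=4, seed=2
        )
        cells = effort.removal_bias_surface(
            trap_grid=(1, 10), day_grid=(4, 20), n_sims=12, seed=2, area_model=am
        )
        by = {(c.effort.n_units, c.effort.n_days): c for c in cells}
        assert by[(10, 20)].abs_scaled_bias < by[(1, 4)].abs_scaled_bias


def test_surface_frame_schema():
    cell = effort.ReductionCell(
        effort=costs.EffortConfig("removal", 3, 14),
        scaled_bias=-0.02,
        variance=0.5,
        cost_usd=4000.0,
        prop_converged=1.0,
        n_replicates=10,
    )
    df = effort.surface_frame([cell])
    assert list(df.columns) == [
        "method", "n_units", "n_days", "scaled_bias", "abs_scaled_bias",
        "variance", "cost_usd", "prop_converged", "n_replicates",
    ]
    assert df.loc[0, "abs_scaled_bias"] == pytest.approx(0.02)
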