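import numpy as np
import pytest
import xarray as xr

from paleopop.hindcast import (analog_screen, cell_area_km2, grid_cell_areas,
                               liebig_minimum, modal_limiting_factor, occupancy,
                               population_size, predict_density_surface,
                               run_hindcast)
from paleopop.predictors import VARIABLE_ORDER
from paleopop.qgam import EnsembleModel, QuantileFit, pspline_knots


def constant_fit(variable_id, value, lo=0.0, hi=10.0, tau=0.5):
    """QuantileFit whose curve is identically `value` on [lo, hi]."""
    return QuantileFit(variable_id=variable_id, tau=tau,
                       knots=pspline_knots(lo, hi, 4),
                       coefficients=np.full(4, value), lam=0.0,
                       train_range=(lo, hi), deviance_explained=0.0, n_train=50)


def constant_ensemble(variable_id, values, lo=0.0, hi=10.0):
    fits = [constant_fit(variable_id, v, lo, hi) for v in values]
    return EnsembleModel(variable_id=variable_id, tau=0.5, fits=fits,
                         fold_train_indices=[np.arange(3)] * len(fits),
                         fold_test_indices=[np.arange(3)] * len(fits),
                         metrics={}, lam=0.0)


def toy_cube(values_by_var, times=None):
    """Predictor cube from (time, lat, lon) arrays."""
    arrays = {k: np.asarray(v, float) for k, v in values_by_var.items()}
    nt, nlat, nlon = next(iter(arrays.values())).shape
    times = times if times is not None else 21.0 - 0.5 * np.arange(nt)
    return xr.Dataset({k: (("time", "lat", "lon"), v) for k, v in arrays.items()},
                      coords={"time": times,
                              "lat": 50.0 - np.arange(nlat),
                              "lon": np.arange(nlon, dtype=float)})


class TestCellArea:
    def test_half_degree_equator_closed_form(self):
        # R²·Δλ·(sin 0.25° − sin −0.25°)
        expected = 6371.0**2 * np.deg2rad(0.5) * 2 * np.sin(np.deg2rad(0.25))
        assert cell_area_km2(0.0, 0.5) == pytest.approx(expected, rel=1e-12)
        assert cell_area_km2(0.0, 0.5) == pytest.approx(3091.0, abs=1.0)

    def test_hemispheric_symmetry(self):
        for lat in (10.0, 45.0, 89.75):
            assert cell_area_km2(lat, 0.5) == pytest.approx(
                cell_area_km2(-lat, 0.5), rel=1e-12)

    def test_global_grid_sums_to_sphere_area(self):
        res = 1.0
        lats = -90.0 + res / 2 + res * np.arange(180)
        areas = grid_cell_areas(lats, 360, res, res)
        assert areas.sum() == pytest.approx(4 * np.pi * 6371.0**2, rel=1e-6)

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError):
            cell_area_km2(95.0, 0.5)


class TestLiebigMinimum:
    def test_two_constant_grids(self):
        a = np.full((4, 4), 1.0)
        b = np.full((4, 4), 0.5)
        dens, codes, tie = liebig_minimum({"ET": a, "TS": b})
        assert np.all(dens == 0.5)
        assert np.all(codes == VARIABLE_ORDER.index("TS"))
        assert not tie.any()

    def test_single_variable_identity(self):
        g = np.random.default_rng(0).uniform(0, 2, (3, 3))
        dens, codes, _ = liebig_minimum({"TAP": g})
        assert np.array_equal(dens, g)
        assert np.all(codes == VARIABLE_ORDER.index("TAP"))

    def test_tie_goes_to_earlier_variable_and_is_flagged(self):
        g = np.full((2, 2), 1.0)
        dens, codes, tie = liebig_minimum({"TS": g.copy(), "ET": g.copy()})
        assert np.all(codes == VARIABLE_ORDER.index("ET"))
        assert tie.all()

    def test_all_nan_cell_is_missing(self):
        a = np.array([[np.nan, 1.0]])
        b = np.array([[np.nan, 2.0]])
        dens, codes, _ = liebig_minimum({"ET": a, "TS": b})
        assert np.isnan(dens[0, 0]) and codes[0, 0] == -1
        assert dens[0, 1] == 1.0

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            grids = {v: rng.uniform(0, 3, (10, 10)) for v in ("ET", "NPP", "TAP")}
            dens, codes, _ = liebig_minimum(grids)
            for i in range(10):
                for j in range(10):
                    best_v, best = None, np.inf
                    for v in ("ET", "NPP", "TAP"):  # Table-order subset
                        if grids[v][i, j] < best:
                            best_v, best = v, grids[v][i, j]
                    assert dens[i, j] == best
                    assert codes[i, j] == VARIABLE_ORDER.index(best_v)

    def test_liebig_never_exceeds_any_component(self):
        rng = np.random.default_rng(7)
        grids = {v: rng.uniform(0, 3, (8, 8)) for v in ("ET", "TS", "TAP")}
        dens, _, _ = liebig_minimum(grids)
        for g in grids.values():
            assert np.all(dens <= g + 1e-15)

    def test_removing_non_limiting_variable_changes_nothing(self):
        rng = np.random.default_rng(8)
        grids = {v: rng.uniform(0, 3, (8, 8)) for v in ("ET", "TS", "TAP")}
        dens, codes, _ = liebig_minimum(grids)
        not_argmin = codes != VARIABLE_ORDER.index("TAP")
        d2, c2, _ = liebig_minimum({k: v for k, v in grids.items() if k != "TAP"})
        assert np.array_equal(dens[not_argmin], d2[not_argmin])
        assert np.array_equal(codes[not_argmin], c2[not_argmin])


class TestOccupancy:
    def test_threshold_is_strict(self):
        dens = np.array([0.2, 0.21, 0.19, np.nan])
        assert occupancy(dens).tolist() == [False, True, False, False]

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        dens = rng.uniform(0, 0.5, (10, 10))
        occ = occupancy(dens)
        assert occ.sum() == sum(dens[i, j] > 0.2
                                for i in range(10) for j in range(10))


class TestPopulationSize:
    def test_uniform_density_closed_form(self):
        # 2 persons/100 km² over 1e6 km² → 20 000 persons
        dens = np.full((10, 10), 2.0)
        areas = np.full((10, 10), 1e6 / 100)
        free = np.ones((10, 10), bool)
        assert population_size(dens, occupancy(dens), free, areas) == pytest.approx(20000.0)

    def test_everything_below_threshold_is_zero(self):
        dens = np.full((5, 5), 0.1)
        areas = np.full((5, 5), 1000.0)
        assert population_size(dens, occupancy(dens), np.ones((5, 5), bool), areas) == 0.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        dens = rng.uniform(0, 1.0, (10, 10))
        areas = rng.uniform(500, 3000, (10, 10))
        ice = rng.random((10, 10)) < 0.3
        occ = occupancy(dens)
        got = population_size(dens, occ, ~ice, areas)
        expected = sum(dens[i, j] / 100.0 * areas[i, j]
                       for i in range(10) for j in range(10)
                       if dens[i, j] > 0.2 and not ice[i, j])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_additive_over_partitions(self):
        rng = np.random.default_rng(3)
        dens = rng.uniform(0, 1.0, (6, 8))
        areas = rng.uniform(500, 3000, (6, 8))
        free = np.ones((6, 8), bool)
        occ = occupancy(dens)
        left = np.zeros_like(free)
        left[:, :4] = True
        total = population_size(dens, occ, free, areas)
        assert total == pytest.approx(
            population_size(dens, occ & left, free, areas)
            + population_size(dens, occ & ~left, free, areas))


class TestModalFactor:
    def test_unanimous(self):
        grids = np.full((5, 3, 3), 2, dtype=np.int16)
        mode, tie = modal_limiting_factor(grids)
        assert np.all(mode == 2) and not tie.any()

    def test_majority(self):
        grids = np.stack([np.full((2, 2), 0), np.full((2, 2), 0),
                          np.full((2, 2), 1)]).astype(np.int16)
        mode, tie = modal_limiting_factor(grids)
        assert np.all(mode == 0) and not tie.any()

    def test_tie_goes_to_fixed_order_and_flags(self):
        grids = np.stack([np.full((2, 2), 5), np.full((2, 2), 1)]).astype(np.int16)
        mode, tie = modal_limiting_factor(grids)
        assert np.all(mode == 1)  # earlier variable in Table order
        assert tie.all()

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(4)
        grids = rng.integers(0, 4, (20, 10, 10)).astype(np.int16)
        mode, _ = modal_limiting_factor(grids)
        for i in range(10):
            for j in range(10):
                counts = np.bincount(grids[:, i, j], minlength=10)
                assert mode[i, j] == int(np.argmax(counts))


class TestAnalogScreen:
    def test_all_inside_all_retained(self):
        ens = {"ET": constant_ensemble("ET", [0.0], lo=0.0, hi=10.0)}
        cube = toy_cube({"ET": np.full((3, 4, 4), 5.0)})
        retained, masks = analog_screen(ens, cube)
        assert all(retained[t] == ["ET"] for t in range(3))
        assert masks is None

    def test_pushed_variable_excluded_only_where_out_of_range(self):
        vals = np.full((5, 4, 4), 5.0)
        vals[2:4] = 12.0  # beyond the training max at steps 2 and 3
        ens = {"ET": constant_ensemble("ET", [0.0], 0.0, 10.0),
               "TS": constant_ensemble("TS", [0.0], 0.0, 10.0)}
        cube = toy_cube({"ET": vals, "TS": np.full((5, 4, 4), 5.0)})
        retained, _ = analog_screen(ens, cube)
        assert retained[0] == ["ET", "TS"]
        assert retained[2] == ["TS"] and retained[3] == ["TS"]
        assert retained[4] == ["ET", "TS"]

    def test_everything_excluded_is_an_error(self):
        ens = {"ET": constant_ensemble("ET", [0.0], 0.0, 1.0)}
        cube = toy_cube({"ET": np.full((2, 3, 3), 99.0)})
        with pytest.raises(RuntimeError):
            analog_screen(ens, cube)

    def test_cell_policy_masks_per_cell(self):
        vals = np.full((1, 2, 2), 5.0)
        vals[0, 0, 0] = 50.0
        ens = {"ET": constant_ensemble("ET", [0.0], 0.0, 10.0)}
        cube = toy_cube({"ET": vals})
        retained, masks = analog_screen(ens, cube, policy="cell")
        assert retained[0] == ["ET"]
        assert not masks["ET"][0, 0, 0] and masks["ET"][0, 1, 1]


class TestPredictDensitySurface:
    def test_identical_perfect_fits_give_constant_grid(self):
        ens = constant_ensemble("ET", [np.log10(2.5)] * 4)
        cube = toy_cube({"ET": np.full((2, 3, 3), 5.0)})
        surf = predict_density_surface(ens, cube, 0)
        assert np.allclose(surf.mean, 2.5)
        assert np.allclose(surf.lo, 2.5) and np.allclose(surf.hi, 2.5)

    def test_single_fold_mean_equals_that_fold(self):
        ens = constant_ensemble("ET", [0.3])
        cube = toy_cube({"ET": np.full((1, 2, 2), 5.0)})
        surf = predict_density_surface(ens, cube, 0)
        assert np.allclose(surf.mean, 10.0 ** 0.3)


class TestRunHindcast:
    def test_constant_world_bookkeeping(self):
        nt, nlat, nlon = 3, 4, 5
        ens = {"ET": constant_ensemble("ET", [0.0, 0.1, -0.1]),
               "TS": constant_ensemble("TS", [0.5, 0.6, 0.4])}
        pc = toy_cube({"ET": np.full((nt, nlat, nlon), 5.0),
                       "TS": np.full((nt, nlat, nlon), 5.0)})
        ice = xr.DataArray(np.zeros((nt, nlat, nlon), bool), coords=pc.coords,
                           dims=("time", "lat", "lon"))
        res = run_hindcast(ens, None, ice, predictor_cube=pc)
        # ET fold-mean density (~1.0) is below TS (~10^0.5): ET limits everywhere
        assert np.all(res.limiting_factor.values == VARIABLE_ORDER.index("ET"))
        assert np.all(res.occupancy.values)
        assert res.series.shape[0] == nt
        expected_pop = float((10.0**0.0 + 10.0**0.1 + 10.0**-0.1) / 3 / 100.0
                             * res.areas_km2.sum())
        assert res.series["pop_size"].iloc[0] == pytest.approx(expected_pop, rel=1e-9)

    def test_ice_masks_factor_and_occupancy(self):
        nt, nlat, nlon = 2, 3, 3
        ens = {"ET": constant_ensemble("ET", [0.5, 0.5])}
        pc = toy_cube({"ET": np.full((nt, nlat, nlon), 5.0)})
        ice_arr = np.zeros((nt, nlat, nlon), bool)
        ice_arr[0, 0, :] = True
        ice = xr.DataArray(ice_arr, coords=pc.coords, dims=("time", "lat", "lon"))
        res = run_hindcast(ens, None, ice, predictor_cube=pc)
        assert np.all(res.limiting_factor.values[0, 0, :] == -1)
        assert not res.occupancy.values[0, 0, :].any()
        assert res.series["occupied_fraction"].iloc[0] == 1.0  # of ice-free cells
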