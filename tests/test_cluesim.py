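"""Markov demand, logistic suitability, iterative allocation and kappa."""

import numpy as np
import pandas as pd
import pytest

import esvdyn as e
from esvdyn.cluesim import (
    AllocationSettings,
    DemandError,
    _demand_to_cells,
)
from esvdyn.grids import CLASS_NAMES, GridAlignmentError


class TestTransitionMatrix:
    def test_identity_for_identical_grids(self, landscape):
        np.testing.assert_allclose(
            e.transition_matrix(landscape, landscape), np.eye(6))

    def test_hand_cross_tabulation(self, toy_grid):
        g0 = toy_grid([[1, 1], [2, 2]])
        g1 = toy_grid([[1, 2], [2, 2]])
        m = e.transition_matrix(g0, g1)
        np.testing.assert_allclose(m[0], [0.5, 0.5, 0, 0, 0, 0])
        np.testing.assert_allclose(m[1], [0, 1, 0, 0, 0, 0])
        np.testing.assert_allclose(m[2:], np.eye(6)[2:])  # absent classes

    def test_rows_stochastic_on_synthetic_pair(self, landscape_pair):
        m = e.transition_matrix(*landscape_pair)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()

    def test_misaligned_rejected(self, landscape, toy_grid):
        with pytest.raises(GridAlignmentError):
            e.transition_matrix(landscape, toy_grid(np.ones((4, 4))))


class TestDemand:
    def test_identity_matrix_constant_demand(self):
        areas = np.array([100.0, 50, 30, 5, 40, 2])
        demand = e.project_demand(areas, np.eye(6), base_year=2020)
        for cls, a in zip(CLASS_NAMES, areas):
            np.testing.assert_allclose(demand[cls], a)

    def test_mass_conservation(self, landscape_pair):
        g0, g1 = landscape_pair
        m = e.transition_matrix(g0, g1)
        areas = e.class_areas(g1)
        demand = e.project_demand(areas, m, base_year=2020)
        totals = demand[list(CLASS_NAMES)].sum(axis=1)
        np.testing.assert_allclose(totals, areas.sum(), rtol=1e-12)

    def test_two_class_toy_interpolation(self):
        m = np.eye(6)
        m[0, 0], m[0, 1] = 0.9, 0.1
        areas = np.array([100.0, 0, 0, 0, 0, 0])
        demand = e.project_demand(areas, m, base_year=2020, step_years=5,
                                  target_years=[2022, 2023, 2025])
        # midpoint year 2022.5 is between rows; check endpoints + linearity
        end = demand[demand.year == 2025].iloc[0]
        assert end["plowland"] == pytest.approx(90.0)
        assert end["forestland"] == pytest.approx(10.0)
        mid = demand[demand.year == 2023].iloc[0]  # frac 0.6
        assert mid["plowland"] == pytest.approx(94.0)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.eye(6) * 0.5
        with pytest.raises(DemandError):
            e.project_demand(np.ones(6), bad, base_year=2020)

    def test_largest_remainder_sums_exactly(self):
        cells = _demand_to_cells(np.array([10.4, 10.3, 10.3, 0, 0, 0.0]),
                                 cell_area=1.0, n_valid=31, tolerance=0.01)
        assert cells.sum() == 31


class TestSuitability:
    def test_learnable_class_has_high_auc(self, landscape, drivers):
        model = e.fit_suitability(landscape, drivers, seed=0)
        # forestland rides the "elevation" driver
        assert model.auc[1] >= 0.9

    def test_separable_class_auc_near_one(self, toy_grid):
        labels = np.ones((16, 16), dtype=np.int64)
        labels[:, 8:] = 2
        grid = toy_grid(labels)
        sep = np.zeros((16, 16))
        sep[:, 8:] = 1.0
        stack = e.DriverStack(("sep", "noise"), np.stack(
            [sep, np.random.default_rng(0).random((16, 16))]))
        model = e.fit_suitability(grid, stack, sample_fraction=1.0, seed=0)
        assert model.auc[1] >= 0.99

    def test_noise_drivers_auc_near_chance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 3, size=(64, 64)).astype(np.int64)
        grid = e.LandUseGrid(labels)
        stack = e.DriverStack(
            ("n1", "n2"), rng.random((2, 64, 64)))
        model = e.fit_suitability(grid, stack, sample_fraction=0.6, seed=1)
        assert 0.45 <= model.auc[0] <= 0.60

    def test_surfaces_match_logistic_formula(self, landscape, drivers):
        model = e.fit_suitability(landscape, drivers, seed=0)
        surfaces = e.suitability_surfaces(model, drivers)
        assert surfaces.shape == (6, *landscape.shape)
        # spot-check one cell by scalar evaluation
        r, c = 10, 20
        x = np.array([(drivers.data[d, r, c] - model.driver_min[d])
                      / model.driver_range[d]
                      for d in range(len(drivers.names))])
        for cls in range(6):
            if not model.fitted_mask[cls]:
                continue
            logit = model.intercepts[cls] + model.coefficients[cls] @ x
            assert surfaces[cls, r, c] == pytest.approx(
                1 / (1 + np.exp(-logit)), abs=1e-9)

    def test_zero_coefficients_give_half(self, drivers):
        model = e.SuitabilityModel(
            driver_names=drivers.names,
            intercepts=np.zeros(6),
            coefficients=np.zeros((6, len(drivers.names))),
            auc=np.zeros(6), fitted_mask=np.ones(6, dtype=bool))
        surfaces = e.suitability_surfaces(model, drivers)
        np.testing.assert_allclose(surfaces, 0.5)

    def test_absent_class_flagged_unfit(self, drivers):
        labels = np.ones((64, 64), dtype=np.int64)
        labels[:10] = 2  # only classes 1 and 2 present
        model = e.fit_suitability(e.LandUseGrid(labels), drivers, seed=0)
        assert not model.fitted_mask[3]
        surfaces = e.suitability_surfaces(model, drivers)
        np.testing.assert_allclose(surfaces[3], 0.0)


@pytest.fixture(scope="module")
def fitted(landscape_pair, drivers):
    g0, _ = landscape_pair
    model = e.fit_suitability(g0, drivers, seed=0)
    return model, e.suitability_surfaces(model, drivers)


class TestAllocate:
    def test_identity_fixpoint(self, landscape, fitted):
        _, surfaces = fitted
        out = e.allocate(landscape, surfaces, e.class_areas(landscape))
        np.testing.assert_array_equal(out.data, landscape.data)

    def test_demand_satisfaction_on_shift(self, landscape, fitted):
        _, surfaces = fitted
        areas = e.class_areas(landscape)
        shift = areas.copy()
        amount = 0.05 * areas[0]
        shift[0] -= amount
        shift[4] += amount
        out = e.allocate(landscape, surfaces, shift)
        achieved = e.class_areas(out)
        n_valid = landscape.valid_mask.sum()
        assert np.abs(achieved - shift).max() <= 0.001 * n_valid \
            * landscape.cell_area + 1.0  # +1 cell for integer apportionment
        assert achieved.sum() == pytest.approx(areas.sum())

    def test_converted_cells_follow_suitability(self, landscape, fitted):
        _, surfaces = fitted
        areas = e.class_areas(landscape)
        shift = areas.copy()
        amount = 0.05 * areas[0]
        shift[0] -= amount
        shift[4] += amount
        out = e.allocate(landscape, surfaces, shift)
        converted = (landscape.data != 5) & (out.data == 5)
        assert converted.any()
        assert surfaces[4][converted].mean() > surfaces[4].mean()

    def test_restricted_cells_never_change(self, landscape, fitted):
        _, surfaces = fitted
        restricted = np.zeros(landscape.shape, dtype=bool)
        restricted[20:30, 20:30] = True
        settings = AllocationSettings(restricted=restricted)
        areas = e.class_areas(landscape)
        shift = areas.copy()
        amount = 0.05 * areas[0]
        shift[0] -= amount
        shift[4] += amount
        out = e.allocate(landscape, surfaces, shift, settings)
        np.testing.assert_array_equal(out.data[restricted],
                                      landscape.data[restricted])

    def test_infeasible_demand_rejected(self, landscape, fitted):
        _, surfaces = fitted
        with pytest.raises(DemandError):
            e.allocate(landscape, surfaces, np.ones(6))  # sums far below area


class TestSimulate:
    def test_zero_change_demand_keeps_sequence(self, landscape, fitted):
        model, _ = fitted
        areas = e.class_areas(landscape)
        demand = pd.DataFrame(
            [{"year": y, **dict(zip(CLASS_NAMES, areas))}
             for y in (2021, 2022)])
        out = e.simulate(landscape, model, _pad_drivers(model, landscape),
                         demand)
        for grid in out.values():
            np.testing.assert_array_equal(grid.data, landscape.data)

    def test_one_year_equals_direct_allocate(self, landscape, drivers, fitted):
        model, surfaces = fitted
        areas = e.class_areas(landscape)
        shift = areas.copy()
        shift[0] -= 20
        shift[4] += 20
        demand = pd.DataFrame([{"year": 2021, **dict(zip(CLASS_NAMES, shift))}])
        out = e.simulate(landscape, model, drivers, demand)
        direct = e.allocate(landscape, surfaces, shift)
        np.testing.assert_array_equal(out[2021].data, direct.data)

    def test_multi_year_conserves_area(self, landscape, drivers, fitted):
        model, _ = fitted
        g0 = landscape
        m = np.eye(6)
        m[0, 0], m[0, 4] = 0.96, 0.04
        demand = e.project_demand(e.class_areas(g0), m, base_year=2020,
                                  step_years=5)
        out = e.simulate(g0, model, drivers, demand)
        total = e.class_areas(g0).sum()
        for grid in out.values():
            assert e.class_areas(grid).sum() == pytest.approx(total)


def _pad_drivers(model, landscape):
    import numpy as np
    return e.DriverStack(model.driver_names,
                         np.zeros((len(model.driver_names),
                                   *landscape.shape)))


class TestKappa:
    def test_identical_maps(self, landscape):
        assert e.kappa(landscape, landscape) == pytest.approx(1.0)

    def test_chance_agreement_near_zero(self, toy_grid):
        # checkerboard vs uniform: agreement equals the chance expectation
        checker = np.indices((16, 16)).sum(axis=0) % 2 + 1
        uniform = np.ones((16, 16), dtype=np.int64)
        k = e.kappa(toy_grid(checker.astype(np.int64)), toy_grid(uniform))
        assert k == pytest.approx(0.0, abs=1e-9)

    def test_label_permutation_invariance(self, landscape_pair):
        g0, g1 = landscape_pair
        perm = {1: 3, 2: 1, 3: 2, 4: 6, 5: 4, 6: 5}
        relabel = np.vectorize(lambda v: perm.get(v, v))
        p0 = e.LandUseGrid(relabel(g0.data).astype(np.int64))
        p1 = e.LandUseGrid(relabel(g1.data).astype(np.int64))
        assert e.kappa(p0, p1) == pytest.approx(e.kappa(g0, g1), rel=1e-12)

    def test_self_validation_on_synthetic_pair(self, landscape_pair, drivers):
        """Simulating t0 -> t1 with the true t1 demand recovers the t1 map
        with strong chance-corrected agreement."""
        g0, g1 = landscape_pair
        model = e.fit_suitability(g0, drivers, seed=0)
        surfaces = e.suitability_surfaces(model, drivers)
        simulated = e.allocate(g0, surfaces, e.class_areas(g1))
        assert e.kappa(g1, simulated) >= 0.7
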