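"""CLUE-S style land-use change simulation.

The workflow couples a non-spatial demand model with a spatial allocator:

1. a Markov step projects per-class area demand from the transition
   probabilities observed between two historical maps, with intermediate
   years linearly interpolated;
2. per-class binary logistic regressions on driver rasters yield
   suitability probability surfaces, checked by ROC AUC;
3. an iterative allocator assigns each cell the class with the highest
   total propensity

       TPROP_i(cell) = P_i(cell) + ELAS_i * [current class == i] + ITER_i

   where ELAS_i in [0, 1] is the conversion-resistance elasticity and the
   class-level offsets ITER_i are adjusted each round in proportion to the
   remaining demand deviation until every class matches its demand within
   tolerance.  Cells in a restricted mask (reservoirs, protected forest)
   never change class.
4. Cohen's kappa against a reference map validates simulated output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .grids import (
    CLASS_NAMES,
    N_CLASSES,
    NODATA,
    DriverStack,
    GridAlignmentError,
    LandUseGrid,
)


class DemandError(ValueError):
    """Demand incompatible with the landscape."""


class AllocationConvergenceError(RuntimeError):
    """Iterative allocation failed to meet demand within tolerance."""

    def __init__(self, residuals: np.ndarray):
        self.residuals = residuals
        super().__init__(
            "allocation did not converge; per-class cell deviations: "
            f"{residuals.tolist()}")


# ---------------------------------------------------------------------------
# Markov demand


def transition_matrix(grid_t0: LandUseGrid, grid_t1: LandUseGrid) -> np.ndarray:
    """Row-stochastic 6x6 transition matrix between two co-registered maps.

    Entry (i, j) is the fraction of class-i cells at t0 that are class j
    at t1; classes absent at t0 get identity rows.
    """
    grid_t0.require_aligned(grid_t1)
    mask = grid_t0.valid_mask
    a = grid_t0.data[mask].ravel() - 1
    b = grid_t1.data[mask].ravel() - 1
    counts = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(counts, (a, b), 1.0)
    row_sums = counts.sum(axis=1)
    matrix = np.eye(N_CLASSES)
    present = row_sums > 0
    matrix[present] = counts[present] / row_sums[present, np.newaxis]
    return matrix


def project_demand(areas: np.ndarray, matrix: np.ndarray, base_year: int,
                   step_years: int = 5,
                   target_years: list[int] | None = None) -> pd.DataFrame:
    """Markov demand schedule: one `step_years` transition step, with
    intermediate years linearly interpolated.

    `areas` are the per-class areas at `base_year`; the matrix is applied
    once to obtain the areas at base_year + step_years.  Returns a frame
    with a `year` column plus one column per class.
    """
    areas = np.asarray(areas, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if areas.shape != (N_CLASSES,) or (areas < 0).any():
        raise DemandError("areas must be a non-negative 6-vector")
    if matrix.shape != (N_CLASSES, N_CLASSES) or (matrix < 0).any() \
            or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise DemandError("transition matrix must be row-stochastic")
    if target_years is None:
        target_years = list(range(base_year + 1, base_year + step_years + 1))

    end = areas @ matrix
    rows = []
    for year in target_years:
        frac = (year - base_year) / step_years
        if not 0 <= frac <= 1:
            raise DemandError(f"target year {year} outside the projection step")
        rows.append({"year": year,
                     **dict(zip(CLASS_NAMES, areas + frac * (end - areas)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Suitability regression


@dataclass
class SuitabilityModel:
    """Per-class binary logistic suitability models on scaled drivers."""

    driver_names: tuple[str, ...]
    intercepts: np.ndarray  # (6,)
    coefficients: np.ndarray  # (6, n_drivers)
    auc: np.ndarray  # (6,)
    fitted_mask: np.ndarray  # (6,) bool, False when a class was absent
    driver_min: np.ndarray = field(default=None)
    driver_range: np.ndarray = field(default=None)

    def coefficient_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients.T, index=list(self.driver_names),
                          columns=list(CLASS_NAMES))
        df.loc["intercept"] = self.intercepts
        df.loc["roc_auc"] = self.auc
        return df


def _scale_drivers(drivers: DriverStack):
    table = drivers.as_table()
    dmin = table.min(axis=0)
    drange = table.max(axis=0) - dmin
    drange[drange == 0] = 1.0
    return (table - dmin) / drange, dmin, drange


def fit_suitability(landscape: LandUseGrid, drivers: DriverStack,
                    sample_fraction: float = 0.5,
                    seed: int = 0) -> SuitabilityModel:
    """Fit one presence/absence logistic model per land class.

    Drivers are min-max scaled to [0, 1]; a random `sample_fraction` of
    the valid cells is used for fitting; ROC AUC is computed on the same
    sample (in-sample concordance).  Classes absent from the sample are
    flagged unfit and later receive suitability 0.
    """
    if drivers.shape != landscape.shape:
        raise GridAlignmentError("drivers not co-registered with landscape")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0, 1]")

    table, dmin, drange = _scale_drivers(drivers)
    labels = landscape.data.ravel()
    valid = labels != NODATA
    idx = np.flatnonzero(valid)
    if len(np.unique(labels[valid])) < 2:
        raise ValueError("suitability regression needs >= 2 classes present")
    rng = np.random.default_rng(seed)
    n_sample = max(int(len(idx) * sample_fraction), 10)
    sample = rng.choice(idx, size=min(n_sample, len(idx)), replace=False)
    x = table[sample]
    y_all = labels[sample]

    n_drv = len(drivers.names)
    intercepts = np.zeros(N_CLASSES)
    coefs = np.zeros((N_CLASSES, n_drv))
    auc = np.zeros(N_CLASSES)
    fitted = np.zeros(N_CLASSES, dtype=bool)
    for c in range(N_CLASSES):
        y = (y_all == c + 1).astype(int)
        if y.min() == y.max():
            continue  # class absent (or universal): unfit
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        model.fit(x, y)
        intercepts[c] = model.intercept_[0]
        coefs[c] = model.coef_[0]
        prob = model.predict_proba(x)[:, 1]
        auc[c] = roc_auc_score(y, prob)
        fitted[c] = True
    return SuitabilityModel(driver_names=drivers.names, intercepts=intercepts,
                            coefficients=coefs, auc=auc, fitted_mask=fitted,
                            driver_min=dmin, driver_range=drange)


def suitability_surfaces(model: SuitabilityModel,
                         drivers: DriverStack) -> np.ndarray:
    """Per-class probability rasters (6, rows, cols) from a fitted model."""
    table = drivers.as_table()
    if model.driver_min is not None:
        table = (table - model.driver_min) / model.driver_range
    logits = model.intercepts[:, np.newaxis] + model.coefficients @ table.T
    probs = 1.0 / (1.0 + np.exp(-logits))
    probs[~model.fitted_mask] = 0.0
    return probs.reshape(N_CLASSES, *drivers.shape)


# ---------------------------------------------------------------------------
# Iterative allocation


@dataclass
class AllocationSettings:
    """Allocator controls.

    Elasticities follow the conversion-resistance convention: 0 = freely
    convertible, 1 = practically frozen.  `tolerance` is the acceptable
    per-class demand deviation as a fraction of the total valid area.
    """

    elasticity: np.ndarray = field(
        default_factory=lambda: np.array([0.75, 0.85, 0.80, 0.90, 0.85, 0.70]))
    restricted: np.ndarray | None = None  # bool mask of frozen cells
    tolerance: float = 0.001
    max_iterations: int = 10000
    step: float = 1.0

    def __post_init__(self) -> None:
        self.elasticity = np.asarray(self.elasticity, dtype=float)
        if self.elasticity.shape != (N_CLASSES,) \
                or ((self.elasticity < 0) | (self.elasticity > 1)).any():
            raise ValueError("elasticities must be 6 values in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _demand_to_cells(demand_areas: np.ndarray, cell_area: float,
                     n_valid: int, tolerance: float) -> np.ndarray:
    """Convert demanded areas to integer cell counts summing to n_valid."""
    demand_areas = np.asarray(demand_areas, dtype=float)
    if (demand_areas < 0).any():
        raise DemandError("demanded areas must be non-negative")
    total_cells = demand_areas.sum() / cell_area
    if abs(total_cells - n_valid) > max(tolerance * n_valid, 0.5):
        raise DemandError(
            f"demand sums to {total_cells:.2f} cells but the landscape has "
            f"{n_valid}")
    raw = demand_areas / cell_area
    if raw.sum() > 0:
        raw = raw * (n_valid / raw.sum())  # absorb rounding slack
    base = np.floor(raw).astype(int)
    short = n_valid - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(short):
        base[order[i % N_CLASSES]] += 1
    return base


def allocate(landscape: LandUseGrid, surfaces: np.ndarray,
             demand_areas: np.ndarray,
             settings: AllocationSettings | None = None) -> LandUseGrid:
    """Allocate one year's demand onto the landscape.

    Converges when every class's allocated cell count is within
    ``tolerance * n_valid`` cells of its demand.  The incoming grid is
    itself the iteration-0 candidate: if it already satisfies demand, no
    cell is converted (this gives the identity fixpoint when demand
    equals current areas).  The class-level offset iteration does the
    bulk of the work; because logistic suitability saturates, many cells
    can be near-tied and offsets alone cannot split such chunks, so a
    deterministic repair pass then flips the few remaining cells with the
    smallest propensity loss until demand is met exactly.  Raises
    AllocationConvergenceError only when demand is infeasible (e.g. a
    restricted mask pins more cells of a class than are demanded).
    """
    if settings is None:
        settings = AllocationSettings()
    surfaces = np.asarray(surfaces, dtype=float)
    if surfaces.shape != (N_CLASSES, *landscape.shape):
        raise GridAlignmentError("suitability surfaces not co-registered")

    valid = landscape.valid_mask.ravel()
    n_valid = int(valid.sum())
    demand_cells = _demand_to_cells(demand_areas, landscape.cell_area,
                                    n_valid, settings.tolerance)
    tol_cells = settings.tolerance * n_valid

    current = landscape.data.ravel()
    frozen = np.zeros_like(valid)
    if settings.restricted is not None:
        frozen = np.asarray(settings.restricted, dtype=bool).ravel()
        if frozen.shape != valid.shape:
            raise GridAlignmentError("restricted mask not co-registered")
    free = valid & ~frozen

    # iteration-0 candidate: the unchanged input grid
    counts = np.bincount(current[valid] - 1, minlength=N_CLASSES)
    dev = demand_cells - counts
    if np.abs(dev).max() <= tol_cells:
        return LandUseGrid(landscape.data.copy(), cell_area=landscape.cell_area,
                           cell_size=landscape.cell_size)

    probs = surfaces.reshape(N_CLASSES, -1)[:, free]
    cur_free = current[free] - 1
    base = probs.copy()
    # elasticity bonus on the current class, plus a tie-break bump so the
    # current class wins exact propensity ties
    base[cur_free, np.arange(base.shape[1])] += \
        settings.elasticity[cur_free] + 1e-9
    frozen_counts = np.bincount(current[valid & frozen] - 1,
                                minlength=N_CLASSES) if frozen.any() \
        else np.zeros(N_CLASSES, dtype=int)

    free_target = demand_cells - frozen_counts
    if (free_target < 0).any():
        raise AllocationConvergenceError(free_target)

    # phase 1: class-level offsets chase the demand deviation; the update
    # is relative to each class's own demand so small classes get a
    # usable signal, and the step is damped on oscillation
    denom = np.maximum(demand_cells, 1.0)
    iter_offset = np.zeros(N_CLASSES)
    step = settings.step
    prev_dev_norm = np.inf
    best_dev_norm = np.inf
    prev_sign = np.zeros(N_CLASSES)
    stall = 0
    tprop = base
    labels = cur_free
    for _ in range(settings.max_iterations):
        tprop = base + iter_offset[:, np.newaxis]
        labels = np.argmax(tprop, axis=0)
        counts = np.bincount(labels, minlength=N_CLASSES) + frozen_counts
        dev = demand_cells - counts
        dev_norm = np.abs(dev).max()
        if dev_norm <= tol_cells:
            break
        if dev_norm < best_dev_norm:
            best_dev_norm, stall = dev_norm, 0
        else:
            stall += 1
            if stall >= 50:
                break  # offsets cannot split near-tied cells; repair below
        sign = np.sign(dev)
        if dev_norm >= prev_dev_norm and (sign * prev_sign < 0).any():
            step = max(step * 0.7, 1e-3)
        prev_dev_norm, prev_sign = dev_norm, sign
        iter_offset += 0.05 * step * dev / denom

    # phase 2: exact repair — move the remaining few cells from
    # over-allocated to under-allocated classes, each time flipping the
    # cell that loses the least total propensity (deterministic)
    counts_free = np.bincount(labels, minlength=N_CLASSES)
    dev = free_target - counts_free
    cell_idx = np.arange(labels.size)
    guard = int(np.abs(dev).sum()) + 1
    while dev.max() > 0 and guard > 0:
        guard -= 1
        under = int(np.argmax(dev))
        movable = (dev[labels] < 0)
        if not movable.any():
            raise AllocationConvergenceError(free_target - counts_free)
        gain = tprop[under, cell_idx] - tprop[labels, cell_idx]
        gain[~movable] = -np.inf
        cell = int(np.argmax(gain))
        dev[labels[cell]] += 1
        counts_free[labels[cell]] -= 1
        labels[cell] = under
        dev[under] -= 1
        counts_free[under] += 1
    if dev.max() > 0:  # pragma: no cover - defensive
        raise AllocationConvergenceError(free_target - counts_free)

    out = current.copy()
    out[free] = labels + 1
    return LandUseGrid(out.reshape(landscape.shape),
                       cell_area=landscape.cell_area,
                       cell_size=landscape.cell_size)


def simulate(landscape_t0: LandUseGrid, model: SuitabilityModel,
             drivers: DriverStack, demand: pd.DataFrame,
             settings: AllocationSettings | None = None
             ) -> dict[int, LandUseGrid]:
    """Chained annual allocation along a demand schedule.

    Each year starts from the previous year's output; suitability
    surfaces are computed once (drivers are static over the horizon).
    """
    surfaces = suitability_surfaces(model, drivers)
    out: dict[int, LandUseGrid] = {}
    current = landscape_t0
    for _, row in demand.sort_values("year").iterrows():
        target = np.array([row[c] for c in CLASS_NAMES], dtype=float)
        current = allocate(current, surfaces, target, settings)
        out[int(row["year"])] = current
    return out


def kappa(reference: LandUseGrid, simulated: LandUseGrid) -> float:
    """Cohen's kappa agreement between two co-registered maps."""
    reference.require_aligned(simulated)
    mask = reference.valid_mask
    if not mask.any():
        raise ValueError("no valid cells to compare")
    return float(cohen_kappa_score(reference.data[mask].ravel(),
                                   simulated.data[mask].ravel()))
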