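"""Equivalent-factor valuation of ecosystem services.

The equivalent-factor method prices the annual service flow of one hectare
of each land class as a dimensionless multiple of a standard unit value
``E_n``, defined as one seventh of the annual grain output value of one
hectare of farmland:

    E_n = (1/7) * P * Q

with P the average grain price (currency/kg) and Q the average grain yield
(kg/ha).  A 9-service x 6-class coefficient table ``VC`` (currency/ha)
then turns class areas into a total ecosystem service value

    ESV = sum_k A_k * VC_k * S * PI

where ``S`` is the biomass adjustment (regional/national NPP ratio) and
``PI`` the socio-economic adjustment (willingness x ability to pay), both
computed per year by :mod:`esvdyn.adjustments`.  Construction land is
valued at zero throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CLASS_NAMES, N_CLASSES, LandUseGrid

#: the nine ecosystem services, grouped into four first-level categories
SERVICES: tuple[str, ...] = (
    "food_production",
    "raw_material",
    "gas_regulation",
    "climate_regulation",
    "hydrological_regulation",
    "waste_treatment",
    "soil_formation_retention",
    "biodiversity_protection",
    "recreation_culture",
)
CATEGORIES: tuple[str, ...] = ("provisioning", "regulating", "supporting", "cultural")
SERVICE_CATEGORY: dict[str, str] = {
    "food_production": "provisioning",
    "raw_material": "provisioning",
    "gas_regulation": "regulating",
    "climate_regulation": "regulating",
    "hydrological_regulation": "regulating",
    "waste_treatment": "supporting",
    "soil_formation_retention": "supporting",
    "biodiversity_protection": "supporting",
    "recreation_culture": "cultural",
}

#: reference per-hectare service values (RMB/ha) for the study region at
#: E_n = 1158.19 RMB/ha; columns follow CLASS_NAMES, construction all zero.
_REFERENCE_EN = 1158.19
_REFERENCE_VALUES = np.array([
    # plow      forest    grass     water      constr  unused
    [1158.19,   382.20,   498.02,   613.84,    0.0,    23.16],
    [451.69,   3451.41,   416.95,   405.37,    0.0,    46.33],
    [833.90,   5003.38,  1737.29,   590.68,    0.0,    69.49],
    [1123.44,  4713.83,  1806.78,  2385.87,    0.0,   150.56],
    [1609.88,  1992.09,  1528.81, 17199.12,    0.0,   301.13],
    [891.81,   4737.00,  1760.45, 21739.23,    0.0,    81.07],
    [1702.54,  4655.92,  2594.35,   474.86,    0.0,   196.89],
    [1181.35,  5223.44,  2165.82,  3972.59,    0.0,   463.28],
    [196.89,   2409.04,  1007.63,  5142.36,    0.0,   277.97],
])


class DomainError(ValueError):
    """Input outside the valuation model's domain."""


@dataclass(frozen=True)
class StandardEquivalent:
    """Standard equivalent factor: value of one seventh of a hectare-year
    of farmland grain output."""

    price: float  # currency per kg
    yield_: float  # kg per hectare

    def __post_init__(self) -> None:
        if self.price <= 0 or self.yield_ <= 0:
            raise DomainError("grain price and yield must be positive")

    @property
    def value(self) -> float:
        """E_n in currency per hectare (full precision)."""
        return self.price * self.yield_ / 7.0

    @property
    def rounded(self) -> float:
        """E_n rounded to 0.01 for reporting."""
        return round(self.value, 2)


def standard_equivalent(price: float, yield_: float) -> StandardEquivalent:
    """Standard equivalent value E_n = (1/7) * P * Q."""
    return StandardEquivalent(price, yield_)


@dataclass(frozen=True)
class ValueCoefficientTable:
    """9 services x 6 classes of per-hectare values (currency/ha)."""

    values: pd.DataFrame  # index SERVICES, columns CLASS_NAMES

    def __post_init__(self) -> None:
        df = self.values
        if list(df.index) != list(SERVICES) or list(df.columns) != list(CLASS_NAMES):
            raise DomainError("value table must be 9 services x 6 classes "
                              "in canonical order")
        if (df.to_numpy() < 0).any():
            raise DomainError("value coefficients must be non-negative")
        if (df["construction"] != 0).any():
            raise DomainError("construction land must be valued at zero")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def column_totals(self) -> pd.Series:
        """Per-class total value of one hectare (sum over the 9 services)."""
        return self.values.sum(axis=0)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ValueCoefficientTable":
        return cls(pd.read_csv(path, index_col=0))


def default_equivalents() -> np.ndarray:
    """Dimensionless 9x6 equivalent matrix of the reference table
    (reference values divided by the reference E_n)."""
    return _REFERENCE_VALUES / _REFERENCE_EN


def build_value_table(equivalents: np.ndarray | None = None,
                      en: float = _REFERENCE_EN) -> ValueCoefficientTable:
    """Scale a dimensionless equivalent matrix by E_n into currency/ha."""
    if equivalents is None:
        equivalents = default_equivalents()
    eq = np.asarray(equivalents, dtype=float)
    if eq.shape != (len(SERVICES), N_CLASSES):
        raise DomainError("equivalents must be a 9x6 matrix")
    if (eq < 0).any():
        raise DomainError("equivalents must be non-negative")
    if (eq[:, CLASS_NAMES.index("construction")] != 0).any():
        raise DomainError("construction column of equivalents must be zero")
    df = pd.DataFrame(eq * en, index=list(SERVICES), columns=list(CLASS_NAMES))
    return ValueCoefficientTable(df)


def class_areas(grid: LandUseGrid) -> np.ndarray:
    """Per-class areas in hectares, canonical class order."""
    return grid.class_counts().astype(float) * grid.cell_area


@dataclass(frozen=True)
class ESVResult:
    """Ecosystem service value of one year, decomposed consistently."""

    year: int | None
    total: float
    by_service: pd.Series  # index SERVICES
    by_category: pd.Series  # index CATEGORIES
    by_class: pd.Series  # index CLASS_NAMES
    contribution_by_class: pd.Series

    def as_row(self) -> dict:
        row = {"year": self.year, "total": self.total}
        row.update({f"service_{k}": v for k, v in self.by_service.items()})
        row.update({f"class_{k}": v for k, v in self.by_class.items()})
        return row


def esv(areas: np.ndarray, table: ValueCoefficientTable,
        s_factor: float = 1.0, pi_factor: float = 1.0,
        year: int | None = None) -> ESVResult:
    """Dynamic ESV of one year: ESV = sum_k A_k * VC_k * S * PI.

    `areas` is the 6-vector of class areas in hectares; `s_factor` and
    `pi_factor` are the biomass and socio-economic adjustments (both 1 for
    the unadjusted static valuation).
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != (N_CLASSES,):
        raise DomainError("areas must be a 6-vector")
    if (areas < 0).any():
        raise DomainError("areas must be non-negative")
    if s_factor <= 0 or pi_factor <= 0:
        raise DomainError("adjustment factors must be positive")

    scale = s_factor * pi_factor
    value_matrix = table.matrix * areas[np.newaxis, :] * scale  # 9x6
    by_service = pd.Series(value_matrix.sum(axis=1), index=list(SERVICES))
    by_class = pd.Series(value_matrix.sum(axis=0), index=list(CLASS_NAMES))
    total = float(value_matrix.sum())
    by_category = pd.Series(
        {c: float(sum(by_service[s] for s in SERVICES if SERVICE_CATEGORY[s] == c))
         for c in CATEGORIES})
    if total > 0:
        contrib = by_class / total
    else:
        contrib = by_class * 0.0
    return ESVResult(year=year, total=total, by_service=by_service,
                     by_category=by_category, by_class=by_class,
                     contribution_by_class=contrib)


@dataclass(frozen=True)
class FishnetESV:
    """Coarse-grid (fishnet) ESV aggregation for two dates and their change."""

    cell_size: float  # metres
    esv_a: np.ndarray
    esv_b: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.esv_b - self.esv_a


def _per_cell_values(grid: LandUseGrid, table: ValueCoefficientTable,
                     s_factor: float, pi_factor: float) -> np.ndarray:
    totals = table.column_totals().to_numpy()
    lookup = np.concatenate(([0.0], totals))  # index 0 = nodata
    return lookup[grid.data] * grid.cell_area * s_factor * pi_factor


def _block_sum(values: np.ndarray, block: int) -> np.ndarray:
    rows, cols = values.shape
    r_edges = np.arange(0, rows, block)
    c_edges = np.arange(0, cols, block)
    return np.add.reduceat(np.add.reduceat(values, r_edges, axis=0),
                           c_edges, axis=1)


def fishnet_esv(grid_a: LandUseGrid, grid_b: LandUseGrid,
                table: ValueCoefficientTable,
                s_a: float = 1.0, pi_a: float = 1.0,
                s_b: float = 1.0, pi_b: float = 1.0,
                cell_size: float = 300.0) -> FishnetESV:
    """ESV change mapped on a coarse fishnet overlay.

    `cell_size` is the fishnet edge in metres and must be a positive
    multiple of the grid cell size (edge fishnet cells may be partial;
    nodata cells contribute zero, so block sums conserve the map total).
    """
    grid_a.require_aligned(grid_b)
    block = int(round(cell_size / grid_a.cell_size))
    if block < 1 or abs(block * grid_a.cell_size - cell_size) > 1e-6:
        raise DomainError("fishnet cell_size must be a multiple of the grid "
                          "cell size")
    vals_a = _per_cell_values(grid_a, table, s_a, pi_a)
    vals_b = _per_cell_values(grid_b, table, s_b, pi_b)
    return FishnetESV(cell_size=cell_size,
                      esv_a=_block_sum(vals_a, block),
                      esv_b=_block_sum(vals_b, block))
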