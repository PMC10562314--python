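"""Seeded synthetic landscapes, drivers and series.

Every downstream stage of the package assumes inputs with a particular
statistical structure: spatially autocorrelated categorical land-use maps
whose composition drifts slowly between years, drivers that are genuinely
informative about class identity (so a suitability regression is
learnable), climate series with interannual noise, and socio-economic
series with smooth quasi-exponential growth (so a GM(1,1) fit is
well-posed).  This module generates all of them deterministically from a
single seed.

Landscapes are built by Gaussian-smoothing seeded white noise and
assigning classes by rank at the quantiles implied by the target class
fractions, which makes the realized composition exact up to integer
rounding.  Year-to-year change relabels only a clustered patch of cells
(the top cells of a fresh smoothed field), so the Hamming distance between
consecutive years is bounded by ``annual_change_rate`` times the cell
count and changes are spatially coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CLASS_NAMES, N_CLASSES, DriverStack, LandUseGrid

#: socio-economic series columns (region = study area, nation = reference)
SOCIO_COLUMNS: tuple[str, ...] = (
    "gdp_region",
    "gdp_nation",
    "engel_rural_region",
    "engel_urban_region",
    "engel_rural_nation",
    "engel_urban_nation",
    "urban_rate_region",
    "urban_rate_nation",
)

_DEFAULT_INITIAL = {
    "gdp_region": 25000.0,
    "gdp_nation": 20000.0,
    "engel_rural_region": 0.36,
    "engel_urban_region": 0.30,
    "engel_rural_nation": 0.38,
    "engel_urban_nation": 0.32,
    "urban_rate_region": 0.45,
    "urban_rate_nation": 0.40,
}

# Region grows slightly slower than the nation so the ability-to-pay ratio
# drifts downward, and Engel coefficients decline as development proceeds.
_DEFAULT_GROWTH = {
    "gdp_region": 0.075,
    "gdp_nation": 0.09,
    "engel_rural_region": -0.012,
    "engel_urban_region": -0.015,
    "engel_rural_nation": -0.014,
    "engel_urban_nation": -0.013,
    "urban_rate_region": 0.012,
    "urban_rate_nation": 0.015,
}


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic study area and its series.

    Defaults describe a plain/mountain city qualitatively: plowland
    dominant, a large forest belt, modest grassland, little water and
    unused land, a growing construction footprint; 2% of cells change
    label per year; temperate climate around 13 degC and ~520 mm rain.
    """

    seed: int = 0
    grid_rows: int = 64
    grid_cols: int = 64
    cell_area: float = 1.0  # hectares per cell
    years: tuple[int, ...] = tuple(range(2000, 2021))
    class_fractions: tuple[float, ...] = (0.46, 0.20, 0.14, 0.02, 0.17, 0.01)
    autocorrelation_scale: float = 3.0  # cells
    annual_change_rate: float = 0.02
    growth_rates: dict = field(default_factory=lambda: dict(_DEFAULT_GROWTH))
    initial_values: dict = field(default_factory=lambda: dict(_DEFAULT_INITIAL))
    socio_noise: float = 0.01  # sd of multiplicative noise on socio series
    climate_mean_sd: tuple[float, float, float, float] = (13.0, 0.6, 520.0, 80.0)

    def __post_init__(self) -> None:
        if len(self.class_fractions) != N_CLASSES:
            raise ConfigurationError("class_fractions must have 6 entries")
        if any(f < 0 for f in self.class_fractions):
            raise ConfigurationError("class_fractions must be non-negative")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("class_fractions must sum to 1")
        if not 0.0 <= self.annual_change_rate <= 0.5:
            raise ConfigurationError("annual_change_rate must lie in [0, 0.5]")
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ConfigurationError("grid dimensions must be at least 8")
        if self.climate_mean_sd[1] < 0 or self.climate_mean_sd[3] < 0:
            raise ConfigurationError("climate standard deviations must be >= 0")
        if self.socio_noise < 0:
            raise ConfigurationError("socio_noise must be >= 0")


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` by `fractions`, summing exactly."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale,
                                   mode="wrap")


def _labels_by_rank(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Assign class codes 1..6 along the sorted order of a continuous field."""
    order = np.argsort(values, axis=None, kind="stable")
    labels = np.empty(values.size, dtype=np.int64)
    start = 0
    for code, cnt in enumerate(counts, start=1):
        labels[order[start:start + cnt]] = code
        start += cnt
    return labels.reshape(values.shape)


def generate_landscape(cfg: SyntheticConfig, year: int) -> LandUseGrid:
    """Land-use grid for `year`, evolved from the first configured year.

    The base year thresholds one smoothed noise field at the exact class
    quantiles; each following year relabels a clustered patch of at most
    ``annual_change_rate * n_cells`` cells, re-apportioning the patch at
    the global class fractions so composition stays near its target.
    """
    if year not in cfg.years:
        raise ConfigurationError(f"year {year} not in configured years")
    shape = (cfg.grid_rows, cfg.grid_cols)
    n_cells = cfg.grid_rows * cfg.grid_cols
    fractions = np.asarray(cfg.class_fractions)

    rng = np.random.default_rng(cfg.seed)
    base = _smooth_field(rng, shape, cfg.autocorrelation_scale)
    labels = _labels_by_rank(base, _largest_remainder(fractions, n_cells))

    k = int(np.floor(cfg.annual_change_rate * n_cells))
    first = cfg.years[0]
    for step in range(1, year - first + 1):
        if k == 0:
            break
        step_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1, step]))
        change = _smooth_field(step_rng, shape, cfg.autocorrelation_scale)
        patch = np.argsort(change, axis=None, kind="stable")[-k:]
        relabel = _smooth_field(step_rng, shape, cfg.autocorrelation_scale)
        patch_vals = relabel.ravel()[patch]
        patch_counts = _largest_remainder(fractions, k)
        new = np.empty(k, dtype=np.int64)
        order = np.argsort(patch_vals, kind="stable")
        start = 0
        for code, cnt in enumerate(patch_counts, start=1):
            new[order[start:start + cnt]] = code
            start += cnt
        flat = labels.ravel()
        flat[patch] = new
        labels = flat.reshape(shape)
    return LandUseGrid(labels, cell_area=cfg.cell_area)


# Class-conditional driver levels; the first two drivers are informative
# about class identity (an "elevation"-like and a "moisture"-like surface),
# the rest are smoothed noise.
_DRIVER_LEVELS = {
    "elevation": (0.25, 0.85, 0.60, 0.15, 0.30, 0.50),
    "moisture": (0.50, 0.60, 0.45, 0.90, 0.30, 0.20),
}
_NOISE_DRIVERS = ("gdp_density", "pop_density", "dist_road", "ndvi")


def generate_drivers(cfg: SyntheticConfig, landscape: LandUseGrid) -> DriverStack:
    """Driver stack co-registered with `landscape`, each band in [0, 1].

    The first two bands mix a class-conditional level (weight 0.75) with
    smoothed noise, so class-conditional means differ by well over 0.2
    between e.g. forestland and plowland; remaining bands are pure
    smoothed noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    shape = landscape.shape
    bands = []
    names = []
    for name, levels in _DRIVER_LEVELS.items():
        level = np.asarray(levels)[landscape.data - 1].astype(float)
        noise = _smooth_field(rng, shape, cfg.autocorrelation_scale)
        noise = (noise - noise.min()) / (np.ptp(noise) or 1.0)
        band = 0.75 * level + 0.25 * noise
        band = (band - band.min()) / (np.ptp(band) or 1.0)
        bands.append(band)
        names.append(name)
    for name in _NOISE_DRIVERS:
        noise = _smooth_field(rng, shape, cfg.autocorrelation_scale)
        noise = (noise - noise.min()) / (np.ptp(noise) or 1.0)
        bands.append(noise)
        names.append(name)
    return DriverStack(tuple(names), np.stack(bands))


def generate_series(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(climate, socio-economic) annual series over ``cfg.years``.

    Climate: Tmp ~ Normal(mean, sd), Pre ~ Normal(mean, sd) truncated at
    1 mm.  Socio-economic: value_t = value_0 (1+g)^t (1+eps_t) with
    eps_t ~ Normal(0, socio_noise), all series positive, Engel
    coefficients and urbanization rates as fractions in (0, 1).
    """
    years = np.asarray(cfg.years)
    t = years - years[0]
    tmp_mean, tmp_sd, pre_mean, pre_sd = cfg.climate_mean_sd

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    tmp = tmp_mean + tmp_sd * rng.standard_normal(len(years))
    pre = np.maximum(pre_mean + pre_sd * rng.standard_normal(len(years)), 1.0)
    climate = pd.DataFrame({"year": years, "tmp": tmp, "pre": pre})

    socio = {"year": years}
    for col in SOCIO_COLUMNS:
        v0 = cfg.initial_values[col]
        g = cfg.growth_rates[col]
        eps = cfg.socio_noise * rng.standard_normal(len(years))
        series = v0 * (1.0 + g) ** t * (1.0 + eps)
        if col.startswith(("engel", "urban")):
            series = np.clip(series, 1e-3, 0.999)
        socio[col] = series
    return climate, pd.DataFrame(socio)


def landscape_series(cfg: SyntheticConfig) -> dict[int, LandUseGrid]:
    """All configured years' landscapes, keyed by year."""
    return {year: generate_landscape(cfg, year) for year in cfg.years}


def class_fraction_table(grid: LandUseGrid) -> pd.Series:
    """Realized class fractions of a grid (diagnostic helper)."""
    counts = grid.class_counts()
    return pd.Series(counts / counts.sum(), index=list(CLASS_NAMES))
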