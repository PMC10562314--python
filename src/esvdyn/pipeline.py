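"""End-to-end assessment and prediction workflows.

``run_assessment`` turns annual land-use grids plus climate and
socio-economic series into per-year adjusted ESV results with optional
fishnet change maps.  ``run_prediction`` extends the chain into the
future: socio-economic indicators are grey-forecast (and graded by the
posterior-error test), the biomass factor comes from scenario climate,
land use is simulated by the Markov + CLUE-S allocator chain, and the
future ESV is assembled year by year with the same valuation model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import adjustments, cluesim, grey, valuation
from .grids import DriverStack, LandUseGrid
from .synthetic import SOCIO_COLUMNS

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Inconsistent pipeline inputs."""


class GreyGradeError(RuntimeError):
    """A grey forecast failed its posterior-error grade under hard-fail."""


@dataclass
class AssessmentReport:
    """Per-year ESV results with the adjustment series behind them."""

    results: dict[int, valuation.ESVResult]
    adjustments: pd.DataFrame
    fishnets: dict[tuple[int, int], valuation.FishnetESV] = field(
        default_factory=dict)
    grey_grades: pd.DataFrame | None = None
    demand: pd.DataFrame | None = None
    simulated: dict[int, LandUseGrid] | None = None

    @property
    def years(self) -> list[int]:
        return sorted(self.results)

    def totals(self) -> pd.Series:
        """Total ESV per year (currency units)."""
        return pd.Series({y: self.results[y].total for y in self.years})

    def totals_1e8(self) -> pd.Series:
        """Total ESV per year in 10^8 currency units, 3 decimals."""
        return (self.totals() / 1e8).round(3)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.results[y].as_row() for y in self.years])

    def contribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {y: self.results[y].contribution_by_class for y in self.years}).T


def run_assessment(landscapes: Mapping[int, LandUseGrid],
                   climate_region: pd.DataFrame,
                   climate_nation: pd.DataFrame,
                   socio: pd.DataFrame,
                   table: valuation.ValueCoefficientTable | None = None,
                   fishnet_pairs: tuple[tuple[int, int], ...] = (),
                   fishnet_cell_size: float = 300.0) -> AssessmentReport:
    """Historical dynamic assessment over the years covered by all inputs.

    Every landscape year must be present in all three series; missing
    years raise a configuration error listing the gaps.
    """
    if table is None:
        table = valuation.build_value_table()
    years = sorted(landscapes)
    series_years = set(climate_region["year"]) & set(climate_nation["year"]) \
        & set(socio["year"])
    gaps = [y for y in years if y not in series_years]
    if gaps:
        raise PipelineConfigError(f"no series data for years: {gaps}")

    sel = lambda df: df[df["year"].isin(years)].sort_values("year") \
        .reset_index(drop=True)
    adj = adjustments.adjustment_series(sel(climate_region),
                                        sel(climate_nation), sel(socio))
    adj_by_year = adj.set_index("year")

    results = {}
    for year in years:
        areas = valuation.class_areas(landscapes[year])
        row = adj_by_year.loc[year]
        results[year] = valuation.esv(areas, table, s_factor=row["s"],
                                      pi_factor=row["pi"], year=year)

    fishnets = {}
    for (a, b) in fishnet_pairs:
        if a not in landscapes or b not in landscapes:
            raise PipelineConfigError(f"fishnet pair ({a}, {b}) not in inputs")
        ra, rb = adj_by_year.loc[a], adj_by_year.loc[b]
        fishnets[(a, b)] = valuation.fishnet_esv(
            landscapes[a], landscapes[b], table,
            s_a=ra["s"], pi_a=ra["pi"], s_b=rb["s"], pi_b=rb["pi"],
            cell_size=fishnet_cell_size)
    return AssessmentReport(results=results, adjustments=adj, fishnets=fishnets)


def forecast_socio(socio: pd.DataFrame, horizon: int,
                   hard_fail: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grey-forecast every socio-economic series `horizon` years ahead.

    Returns (future socio frame, grade frame with a/u/C/P per series).
    Series failing the posterior grade (P > 0.95, C < 0.35) are logged as
    warnings, or raise when `hard_fail` is set.
    """
    socio = socio.sort_values("year").reset_index(drop=True)
    if len(socio) < 4:
        raise PipelineConfigError("grey forecasting needs >= 4 historical years")
    last_year = int(socio["year"].iloc[-1])
    future_years = list(range(last_year + 1, last_year + horizon + 1))
    out = {"year": future_years}
    grades = []
    for col in SOCIO_COLUMNS:
        model, fc, grade = grey.fit_and_forecast(socio[col].to_numpy(), horizon)
        if col.startswith(("engel", "urban")):
            fc = np.clip(fc, 1e-3, 0.999)
        out[col] = fc
        grades.append({"series": col, "a": model.a, "u": model.u,
                       "c": grade.c, "p": grade.p, "passed": grade.passed})
        if not grade.passed:
            msg = (f"grey fit for {col} failed the posterior grade "
                   f"(C={grade.c:.3f}, P={grade.p:.3f})")
            if hard_fail:
                raise GreyGradeError(msg)
            logger.warning(msg)
    return pd.DataFrame(out), pd.DataFrame(grades)


def run_prediction(landscapes: Mapping[int, LandUseGrid],
                   drivers: DriverStack,
                   socio: pd.DataFrame,
                   scenario_climate_region: pd.DataFrame,
                   scenario_climate_nation: pd.DataFrame,
                   horizon: int = 5,
                   table: valuation.ValueCoefficientTable | None = None,
                   settings: cluesim.AllocationSettings | None = None,
                   sample_fraction: float = 0.5,
                   seed: int = 0,
                   hard_fail: bool = False) -> AssessmentReport:
    """Coupled prediction: grey-forecast factors + simulated land use.

    `landscapes` must contain at least two historical years; the last two
    supplied years define the Markov transition step, and the last year's
    grid seeds the spatial simulation.  Scenario climate frames must
    cover the `horizon` future years.  With horizon 0 the report reduces
    to the last historical year's assessment.
    """
    if table is None:
        table = valuation.build_value_table()
    hist_years = sorted(landscapes)
    if len(hist_years) < 2:
        raise PipelineConfigError("prediction needs two historical grids for "
                                  "the Markov step")
    y0, y1 = hist_years[-2], hist_years[-1]
    base_grid = landscapes[y1]

    if horizon == 0:
        hist_region = scenario_climate_region[
            scenario_climate_region["year"] == y1]
        hist_nation = scenario_climate_nation[
            scenario_climate_nation["year"] == y1]
        return run_assessment({y1: base_grid}, hist_region, hist_nation,
                              socio[socio["year"] == y1], table=table)

    future_socio, grades = forecast_socio(socio, horizon, hard_fail=hard_fail)
    future_years = list(future_socio["year"])

    sel = lambda df: df[df["year"].isin(future_years)].sort_values("year") \
        .reset_index(drop=True)
    region = sel(scenario_climate_region)
    nation = sel(scenario_climate_nation)
    missing = [y for y in future_years if y not in set(region["year"])
               or y not in set(nation["year"])]
    if missing:
        raise PipelineConfigError(
            f"scenario climate missing for years: {missing}")
    adj = adjustments.adjustment_series(region, nation, future_socio)
    adj_by_year = adj.set_index("year")

    matrix = cluesim.transition_matrix(landscapes[y0], landscapes[y1])
    step = y1 - y0
    demand = cluesim.project_demand(valuation.class_areas(base_grid), matrix,
                                    base_year=y1, step_years=max(step, horizon),
                                    target_years=future_years)
    model = cluesim.fit_suitability(base_grid, drivers,
                                    sample_fraction=sample_fraction, seed=seed)
    simulated = cluesim.simulate(base_grid, model, drivers, demand, settings)

    results = {}
    for year in future_years:
        areas = valuation.class_areas(simulated[year])
        row = adj_by_year.loc[year]
        results[year] = valuation.esv(areas, table, s_factor=row["s"],
                                      pi_factor=row["pi"], year=year)
    return AssessmentReport(results=results, adjustments=adj,
                            grey_grades=grades, demand=demand,
                            simulated=simulated)
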