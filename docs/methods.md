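# Methods

`esvdyn` implements a dynamic (continuous time-series) assessment and
prediction chain for ecosystem service value (ESV) on categorical
land-use rasters, together with the synthetic data generator used to
exercise it.  This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic conditions
do and do not show about real data.

## Valuation model

The equivalent-factor method prices one hectare-year of each of six land
classes (plowland, forestland, grassland, water, construction, unused)
across nine services (food production, raw material; gas, climate and
hydrological regulation; waste treatment, soil formation & retention,
biodiversity protection; recreation & culture).  The unit of account is
the standard equivalent

E_n = (1/7) · P · Q,

one seventh of the annual grain output value of a hectare of farmland
(P: grain price, currency/kg; Q: grain yield, kg/ha).  A dimensionless
9×6 equivalent matrix scaled by E_n gives the value-coefficient table
VC (currency/ha); the built-in default matrix is the package's reference
table divided by its reference E_n of 1158.19 RMB/ha, and any other
equivalent matrix can be supplied.  Construction land is valued at zero
throughout (heavily human-dominated land is treated as providing no
priced ecosystem services), and the table constructor enforces this.

The annual valuation is

ESV_t = Σ_k A_{k,t} · VC_k · S_t · PI_t,

linear in areas and in both adjustment factors, so decomposition by
service, by category and by class is exact (asserted to 1e-6 relative
in the report invariants).  Monetary values are carried at full
precision internally, reported at 0.01 currency units, and aggregate
tables use 10^8-unit ("hundred-million") scaling with 3 decimals.

A scalar S per year is applied to all classes.  The biomass factor is
defined as a single region-wide NPP ratio, so a per-class vector would
carry no extra information here; the `esv` signature takes scalars and
the extension to class-specific factors is a matter of broadcasting,
not redesign.

Fishnet change maps aggregate per-cell values into coarse blocks
(default 300 m edge, any multiple of the cell size; edge blocks may be
partial).  Nodata cells contribute zero, so the block sums conserve the
map total exactly — partially covered blocks are valued on their
covered area only.

## Adjustment factors

**Biomass factor** S_t = NPP_region,t / NPP_nation,t, with NPP from the
Thornthwaite–Memorial (Lieth) climate relation:

L = 3000 − 25·Tmp + 0.05·Tmp³,
V = 1.05·Pre / sqrt(1 + (1 + 1.05·Pre/L)²),
NPP = 3000 · (1 − e^{−0.0009695·(V−20)}),

with Tmp the annual mean temperature (°C) and Pre the annual
precipitation (mm).  The raw expression is negative for V < 20
(near-desert precipitation); NPP is floored at 0 because productivity
is physically non-negative, and the ratio then raises a domain error if
the national NPP is zero.  Lieth's formula natively yields
g dry matter·m⁻²·yr⁻¹; only the ratio enters the valuation, so units
cancel and no conversion is applied.  Extreme temperatures driving
L ≤ 0 are rejected as out of the formula's domain.  National climate is
taken as a scalar annual series; its provenance (station mean,
area-weighted raster mean, reanalysis) is the caller's choice.

**Socio-economic factor** PI_t = W_t · A_t.  The willingness-to-pay
ratio W_t = W_region/W_nation uses the logistic parameter

W = 2 / (1 + e^{−m}),  m = 1/En_t − 2.5,

where En_t is the population-weighted Engel coefficient
En_t = En_rural·P_rural + En_urban·P_urban (P_urban is the urbanization
rate).  Engel coefficients are treated as fractions in (0, 1), which
anchors W = 1 exactly at En = 0.4 (the logistic midpoint m = 0) and
gives W its full (0, 2) range over realistic Engel values; with
percent-style inputs m would sit near −2.5 for every plausible value
and W would degenerate, so inputs above 1.5 are auto-detected as
percentages, divided by 100 and logged.  The ability-to-pay ratio is
A_t = GDP_region/GDP_nation per capita.  Both factors are scale-free:
multiplying regional and national inputs by any common constant leaves
them unchanged.

Factors are computed for each year separately — no multi-year
averaging — because year-specific coefficients are precisely what makes
the assessment dynamic; `adjustment_series` is the exact composition of
the atomic operations, with no hidden smoothing.

## Land-use simulation

**Demand.**  The 6×6 transition matrix between two historical maps
(entry i,j = fraction of class-i cells that became class j; identity
rows for absent classes) is applied once to the latest areas for one
projection step, and intermediate years are linearly interpolated.  A
single step (not an annualized matrix root) is used: the observed
transition already is a step-length probability, and rooting a
stochastic matrix is neither unique nor guaranteed stochastic.  When
the requested horizon exceeds the historical step length the horizon is
used as the step, i.e. the observed transition is stretched over the
projection window.

**Suitability.**  One binary logistic regression per class (presence vs
absence) on min-max-scaled drivers, fit by scikit-learn on a random
sample of cells (default 50%, seeded), with in-sample ROC AUC by the
rank statistic as the adequacy diagnostic.  No train/test split is
used: the AUC here answers "can the drivers explain the current
pattern", not "does the model generalize".  Classes absent from the
sample are flagged unfit and receive suitability 0.

**Allocation.**  Each unfrozen cell takes the class maximizing

TPROP_i = P_i + ELAS_i·[current class = i] + ITER_i,

with conversion elasticities ELAS in [0, 1] (0 freely convertible, 1
practically frozen; defaults 0.75/0.85/0.80/0.90/0.85/0.70 in class
order — sticky forest and water, mobile plowland and unused land).
Demands are converted to integer cell counts by largest-remainder
apportionment so they sum exactly to the valid-cell total.  The
class-level offsets ITER_i are adjusted each round proportionally to
each class's own remaining deviation (step·dev_i/max(demand_i, 1),
scaled by 0.05, damped ×0.7 on oscillation with a floor of 1e-3):
normalizing by the class's demand rather than the total area keeps the
signal usable for classes occupying ~1% of the map.  Because logistic
suitabilities saturate, many cells can be near-tied and class-level
offsets cannot split such chunks; a deterministic repair pass therefore
flips the few remaining cells — always the cell losing the least total
propensity — until every class meets its integer demand exactly.  A
convergence error (carrying per-class residuals) is raised only for
infeasible demand, e.g. a restricted mask pinning more cells of a class
than are demanded.

Ties in the argmax go to the current class (via an epsilon bump of
1e-9, far below any meaningful propensity difference) and then to the
fixed class order; this determinism also yields the identity fixpoint:
the incoming grid is the iteration-0 candidate, so when demand already
equals current areas within tolerance no cell is converted.  Restricted
cells are excluded from reallocation entirely and count toward the
allocated totals.

Multi-year simulation chains annual allocations, each starting from the
previous output, with suitability surfaces computed once (drivers are
static over the horizon).  Validation uses Cohen's kappa over valid
cells.

## Grey forecasting

GM(1,1) fits the whitened equation dx1/dt + a·x1 = u on the accumulated
series, estimating (a, u) by least squares with mean background values
z(k) = (x1[k] + x1[k−1])/2 — the canonical discretization that makes
the time-response solution the fitted curve.  Fitted and forecast
values come from differencing the response; the first observation is
reproduced exactly by construction.  For |a| < 1e-12 the a→0 limit
(linear accumulated response, constant increments) is used to avoid
dividing by a vanishing coefficient — this is the constant-series case.

The posterior-error test uses population standard deviations (ddof
configurable): C = S2/S1 with S1 the SD of the data and S2 the SD of
the residuals, and P the fraction of residuals within 0.6745·S1 of the
mean residual; a fit passes at P > 0.95 and C < 0.35.  A constant
series has S1 = 0 and is graded C = 0, P = 1 rather than erroring, so
flat synthetic inputs flow through the pipeline.  The pipeline forecast
horizon defaults to 5 years.  Forecast Engel and urbanization series
are clipped into (0, 1) as a guard; over realistic horizons the clip is
inactive.

## Synthetic data

The generator replaces the study-scale inputs (multi-decadal land-cover
rasters, climate grids, statistical-yearbook series) with seeded
constructs that preserve exactly the structure the method consumes:

* **Landscapes** — smoothed white noise (Gaussian kernel, default scale
  3 cells, wrapped boundaries) thresholded by rank at the target class
  fractions, so realized composition is exact to integer rounding and
  patches are spatially coherent.  Year-to-year change relabels only
  the top `annual_change_rate · n_cells` cells of a fresh smoothed
  field (default 2%/yr — the scale of observed decadal land-use churn
  in rapidly urbanizing regions), so consecutive maps differ in at most
  that many cells and changes are clustered.
* **Drivers** — two bands mix a class-conditional level (weight 0.75)
  with smoothed noise, guaranteeing learnable class associations
  (class-conditional mean gaps well above 0.2); four further bands are
  pure smoothed noise.  All bands are min-max scaled to [0, 1].
* **Series** — climate is Gaussian around configurable means (defaults
  13 °C ± 0.6, 520 mm ± 80: a temperate semi-humid setting);
  socio-economic series follow value_t = value_0·(1+g)^t·(1+ε_t) with
  ε ~ N(0, 0.01), the quasi-exponential regime in which GM(1,1) is
  well-posed.  Defaults: regional GDP growth 7.5% vs national 9% (so
  the ability ratio drifts down), Engel coefficients declining ~1.2–1.5
  %/yr from 0.28–0.38, urbanization rising from 0.40–0.45.  Default
  class fractions (0.46, 0.20, 0.14, 0.02, 0.17, 0.01) sketch a
  plain/mountain city: dominant plowland, a forest belt, a large
  construction footprint, little water and unused land.

Everything is deterministic given the configuration: all randomness
flows through `numpy` generators seeded from the single config seed via
fixed-purpose `SeedSequence` offsets.

What the synthetic conditions do **not** emulate: real terrain
(drainage, road networks, administrative geometry), class-specific
transition asymmetries driven by policy, spatially varying climate,
measurement error in yearbook series, or classification error in
land-cover products.  Passing tests therefore demonstrate that the
chain is internally correct and that the allocator/forecaster recover
structure they are designed to recover — not that any particular
empirical ESV trajectory is reproduced.  Study-scale figures (e.g.
multi-billion-yuan regional totals) require the original data products
and are out of scope.

## Problem sizes and defaults

The default study area is 64×64 cells of 1 ha over 2000–2020 with a
5-year prediction horizon — large enough for stable class statistics
(composition fidelity is tested at ±2 pp on 128×128) and demanding
enough to exercise every stage, while a full pipeline run completes in
well under a minute.  Grey fits use series of length 10–21; the
posterior-grade pass-rate condition uses 20 seeds at 1% multiplicative
noise.

## Known limitations

* The willingness-to-pay formula's development-stage index m rises as
  the Engel coefficient falls; the formula is implemented as written
  even though prose descriptions of m sometimes read the opposite way.
* The allocator treats drivers as static over the simulation horizon;
  feedback of simulated land use onto drivers (e.g. distance to new
  construction) is not modelled.
* Demand projection trusts the single observed transition matrix;
  structural breaks in land policy are outside the model class.
* GM(1,1) is a pure-trend model: it cannot represent turning points,
  and series that are not approximately exponential will fail the
  posterior grade (which is the intended guard, not a defect).
* File I/O is plain-text (ESRI ASCII grids, CSV); georeferencing is
  limited to cell size and area, which is sufficient for co-registered
  single-region workflows but not for reprojection or mosaicking.
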