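# esvdyn

Dynamic ecosystem-service-value (ESV) assessment and prediction for
categorical land-use rasters: equivalent-factor valuation with annually
varying biomass and socio-economic adjustment coefficients, a CLUE-S
style spatial land-use change simulator, and GM(1,1) grey forecasting,
coupled into historical-assessment and future-prediction pipelines.

It is written for landscape ecologists and regional planners who want a
tested, scriptable implementation of the dynamic equivalent-factor
workflow — and a seeded synthetic study area to exercise it on — rather
than a chain of one-off GIS operations.

## The model

The unit of account is the **standard equivalent**

    E_n = (1/7) · P · Q

(one seventh of the annual grain output value of one hectare of
farmland; P = grain price, Q = grain yield).  Scaling a dimensionless
9-service × 6-class equivalent matrix by E_n gives per-hectare value
coefficients VC_k, and the annual valuation is

    ESV_t = Σ_k A_{k,t} · VC_k · S_t · PI_t

where A_k are class areas, **S_t = NPP_region/NPP_nation** is a biomass
factor from the Thornthwaite–Memorial climate NPP relation, and
**PI_t = W_t · A_t** combines a willingness-to-pay ratio (logistic in
the population-weighted Engel coefficient, W = 2/(1+e^{−m}) with
m = 1/En − 2.5) with an ability-to-pay ratio (regional/national
per-capita GDP).  Both factors are recomputed for every year — that is
what makes the assessment dynamic.

Prediction couples two models: **GM(1,1)** (dx¹/dt + a·x¹ = u on the
accumulated series, graded by the posterior-error test P > 0.95,
C < 0.35) forecasts the socio-economic indicators, while a **CLUE-S**
style simulator — Markov transition demand, per-class logistic
suitability surfaces with ROC validation, and an elasticity- and
constraint-aware iterative allocator validated by Cohen's kappa —
projects the land-use maps.  See `docs/methods.md` for the full
formulation and numerical choices.

## Worked example

```python
import numpy as np
import esvdyn as e

en = e.standard_equivalent(price=1.23, yield_=6591.33)
table = e.build_value_table()
result = e.esv(np.array([1.0, 0, 0, 0, 0, 0]), table)  # 1 ha plowland
print(en.rounded, result.total)
```

prints `1158.19 9149.69...`: the standard equivalent is 1158.19 RMB/ha,
and one hectare of plowland with no adjustment (S = PI = 1) is worth
the plowland column total of the coefficient table, ≈ 9149.70 RMB/yr.

The full synthetic pipeline (`python examples/full_pipeline.py`) builds
a 64×64 study area over 2000–2020 plus a 5-year prediction and prints,
among other things:

```
historical ESV (x10^8 RMB):
  2000: 0.589   2010: 0.559   2020: 0.501
fishnet change map: 8x8 cells of 800 m, net change -0.088 x10^8 RMB
...
predicted ESV (x10^8 RMB):
  2021: 0.435
  2022: 0.373
  ...
```

Historical totals drift down as construction expands and the
socio-economic factor declines; the fishnet map localizes where value
was gained or lost; the predicted totals combine simulated land use
with grey-forecast adjustment factors (every grey fit's posterior grade
is printed alongside).  The other scripts in `examples/` each walk one
capability: `valuation_basics.py`, `adjustment_factors.py`,
`grey_forecast.py`, `landuse_simulation.py`.

A thin CLI mirrors the library for shell use:

```sh
esvdyn synth --out data/ --seed 3
esvdyn value --landuse data/landuse_2000.asc --out esv.csv
esvdyn forecast-grey --series gdp.csv --horizon 5 --out fc.csv
```

## Layout

- `src/esvdyn/synthetic.py` — seeded synthetic landscapes, drivers, series
- `src/esvdyn/valuation.py` — standard equivalent, value table, ESV, fishnet
- `src/esvdyn/adjustments.py` — NPP, biomass factor, willingness/ability, PI
- `src/esvdyn/grey.py` — GM(1,1) fit, forecast, posterior-error test
- `src/esvdyn/cluesim.py` — Markov demand, suitability, allocation, kappa
- `src/esvdyn/pipeline.py` — assessment and prediction orchestration
- `src/esvdyn/cli.py` — thin command-line wrapper
- `docs/methods.md` — models, defaults, numerical decisions, limitations
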