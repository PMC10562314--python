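"""Annual biomass and socio-economic adjustment factors.

S is the regional/national ratio of climate-derived net primary
productivity; PI multiplies a willingness-to-pay ratio (logistic in the
population-weighted Engel coefficient) by an ability-to-pay ratio
(regional over national per-capita GDP).
"""

import pandas as pd

import esvdyn as e

# NPP from annual mean temperature (degC) and precipitation (mm)
print("Thornthwaite-Memorial NPP:")
for tmp, pre in [(0.0, 1000.0), (13.0, 520.0), (11.5, 600.0)]:
    print(f"  Tmp={tmp:5.1f}  Pre={pre:7.1f}  ->  "
          f"NPP={e.npp_thornthwaite(tmp, pre):8.2f}")

s = e.biomass_factor(e.npp_thornthwaite(13.0, 520.0),
                     e.npp_thornthwaite(11.5, 600.0))
print(f"biomass factor S (warm-dry region / cool-wet nation) = {s:.3f}")

# willingness to pay: W = 1 exactly at the Engel midpoint 0.4
for engel in (0.40, 0.30, 0.25):
    print(f"Engel {engel:.2f} -> W = {e.willingness_parameter(engel):.3f}")

# a 5-year series, assembled year by year
years = list(range(2016, 2021))
climate_region = pd.DataFrame({"year": years, "tmp": 13.0,
                               "pre": [480, 530, 510, 560, 540]})
climate_nation = pd.DataFrame({"year": years, "tmp": 11.5, "pre": 600.0})
socio = pd.DataFrame({
    "year": years,
    "gdp_region": [58e3, 61e3, 64e3, 66e3, 68e3],
    "gdp_nation": [54e3, 60e3, 66e3, 71e3, 72e3],
    "engel_rural_region": 0.24, "engel_urban_region": 0.23,
    "engel_rural_nation": 0.28, "engel_urban_nation": 0.27,
    "urban_rate_region": [0.62, 0.63, 0.64, 0.65, 0.66],
    "urban_rate_nation": [0.57, 0.59, 0.60, 0.61, 0.63],
})
adj = e.adjustment_series(climate_region, climate_nation, socio)
print("\nper-year factors (no multi-year averaging):")
print(adj[["year", "s", "w_t", "a_t", "pi"]].round(3).to_string(index=False))
# S < 1: the region is less productive than the national benchmark here;
# PI tracks the GDP ratio times the Engel-driven willingness ratio.
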