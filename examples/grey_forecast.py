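"""GM(1,1) grey forecasting of a short socio-economic series.

The grey model fits an exponential trend through the accumulated series
and is graded by the posterior-error test: C = residual SD / data SD and
P = share of residuals within 0.6745 data-SDs of the mean residual;
adequate for prediction when P > 0.95 and C < 0.35.
"""

import numpy as np

import esvdyn as e

rng = np.random.default_rng(1)
years = np.arange(2011, 2021)
gdp = 40e3 * 1.07 ** np.arange(10) * (1 + 0.01 * rng.standard_normal(10))

model, fc, grade = e.fit_and_forecast(gdp, horizon=5)
print(f"development coefficient a = {model.a:.5f}")
print(f"grey action quantity   u = {model.u:.1f}")
print(f"posterior grade: C = {grade.c:.3f}, P = {grade.p:.2f} "
      f"({'adequate' if grade.passed else 'inadequate'})")

print("\nyear   observed     fitted")
for y, obs, fit in zip(years, gdp, model.fitted):
    print(f"{y}   {obs:9.1f}  {fit:9.1f}")
print("\nforecast:")
for y, v in zip(range(2021, 2026), fc):
    print(f"{y}              {v:9.1f}")
# a < 0 means growth: forecasts continue the fitted exponential trend.
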