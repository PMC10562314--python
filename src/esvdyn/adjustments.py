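"""Annual biomass and socio-economic adjustment factors.

Two scalar coefficients modulate the static per-hectare values year by
year:

* the biomass factor ``S = NPP_region / NPP_nation``, where NPP is
  estimated from annual mean temperature and annual precipitation with
  the Thornthwaite-Memorial relation (Lieth's climate NPP model);
* the socio-economic factor ``PI = W_t * A_t``, the product of a
  willingness-to-pay ratio (regional over national logistic
  willingness parameter, driven by population-weighted Engel
  coefficients) and an ability-to-pay ratio (regional over national
  per-capita GDP).

Both factors are dimensionless ratios, so any common unit convention in
the NPP or GDP inputs cancels.  Coefficients are computed for every year
separately; no multi-year averaging is applied, which is the point of a
dynamic (continuous-series) assessment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    """Input outside the adjustment model's domain."""


class SeriesMismatchError(ValueError):
    """Input series do not cover the same years."""


# ---------------------------------------------------------------------------
# Biomass factor (NPP ratio)


def npp_thornthwaite(tmp: float, pre: float) -> float:
    """Climate NPP from annual mean temperature (degC) and precipitation (mm).

        L   = 3000 - 25*Tmp + 0.05*Tmp^3
        V   = 1.05*Pre / sqrt(1 + (1 + 1.05*Pre/L)^2)
        NPP = 3000 * (1 - exp(-0.0009695*(V - 20)))

    The raw expression is negative for V < 20 (near-zero precipitation);
    since NPP is physically non-negative the result is floored at 0.
    """
    if pre < 0:
        raise DomainError("precipitation must be non-negative")
    L = 3000.0 - 25.0 * tmp + 0.05 * tmp**3
    if L <= 0:
        raise DomainError(f"evapotranspiration scale L <= 0 at Tmp={tmp}")
    v = 1.05 * pre / np.sqrt(1.0 + (1.0 + 1.05 * pre / L) ** 2)
    npp = 3000.0 * (1.0 - np.exp(-0.0009695 * (v - 20.0)))
    return float(max(npp, 0.0))


def biomass_factor(npp_region: float, npp_nation: float) -> float:
    """S = NPP_region / NPP_nation."""
    if npp_nation <= 0:
        raise DomainError("national NPP must be positive (degenerate climate "
                          "input)")
    if npp_region < 0:
        raise DomainError("regional NPP must be non-negative")
    return npp_region / npp_nation


# ---------------------------------------------------------------------------
# Socio-economic factor (willingness x ability to pay)


def _as_fraction(value: float, name: str) -> float:
    """Accept percent-style inputs (e.g. Engel 36.5) by scaling to fractions."""
    if value > 1.5:
        logger.warning("%s=%s looks like a percentage; dividing by 100",
                       name, value)
        return value / 100.0
    return value


def engel_composite(engel_rural: float, engel_urban: float,
                    prop_rural: float, prop_urban: float) -> float:
    """Population-weighted Engel coefficient
    En_t = En_rural * P_rural + En_urban * P_urban."""
    engel_rural = _as_fraction(engel_rural, "engel_rural")
    engel_urban = _as_fraction(engel_urban, "engel_urban")
    prop_rural = _as_fraction(prop_rural, "prop_rural")
    prop_urban = _as_fraction(prop_urban, "prop_urban")
    if abs(prop_rural + prop_urban - 1.0) > 1e-9:
        raise DomainError("rural and urban population proportions must sum to 1")
    if not (0 < engel_rural < 1 and 0 < engel_urban < 1):
        raise DomainError("Engel coefficients must lie in (0, 1)")
    return engel_rural * prop_rural + engel_urban * prop_urban


def willingness_parameter(engel: float) -> float:
    """Logistic willingness-to-pay parameter.

        m = 1/En_t - 2.5;  W = 2 / (1 + exp(-m))

    With Engel coefficients as fractions, W = 1 exactly at En_t = 0.4 (the
    logistic midpoint) and W -> 2 as En_t -> 0; W lies in (0, 2).
    """
    engel = _as_fraction(engel, "engel")
    if not 0 < engel < 1:
        raise DomainError("Engel coefficient must lie in (0, 1)")
    m = 1.0 / engel - 2.5
    return 2.0 / (1.0 + np.exp(-m))


def willingness_ratio(w_region: float, w_nation: float) -> float:
    """W_t = W_region / W_nation."""
    if w_nation <= 0:
        raise DomainError("national willingness parameter must be positive")
    return w_region / w_nation


def ability_ratio(gdp_region, gdp_nation):
    """A_t = regional / national per-capita GDP (scalar or elementwise)."""
    gdp_region = np.asarray(gdp_region, dtype=float)
    gdp_nation = np.asarray(gdp_nation, dtype=float)
    if (gdp_region <= 0).any() or (gdp_nation <= 0).any():
        raise DomainError("per-capita GDP must be positive")
    out = gdp_region / gdp_nation
    return float(out) if out.ndim == 0 else out


def socio_economic_factor(w_t: float, a_t: float) -> float:
    """PI = W_t * A_t."""
    if w_t <= 0 or a_t <= 0:
        raise DomainError("willingness and ability ratios must be positive")
    return w_t * a_t


# ---------------------------------------------------------------------------
# Annual assembly


def adjustment_series(climate_region: pd.DataFrame,
                      climate_nation: pd.DataFrame,
                      socio: pd.DataFrame) -> pd.DataFrame:
    """Per-year S and PI with their ingredients.

    Inputs are annual tables: climate frames with columns
    ``year, tmp, pre`` (region and nation), and a socio-economic frame
    with columns ``year, gdp_region, gdp_nation, engel_rural_region,
    engel_urban_region, engel_rural_nation, engel_urban_nation,
    urban_rate_region, urban_rate_nation``.  All three must cover exactly
    the same years.  Returns one row per year with columns
    ``npp_region, npp_nation, s, en_region, en_nation, w_region,
    w_nation, w_t, a_t, pi``.
    """
    years = list(climate_region["year"])
    for other, label in ((climate_nation, "national climate"),
                         (socio, "socio-economic")):
        if list(other["year"]) != years:
            raise SeriesMismatchError(
                f"{label} series years differ from regional climate years")

    rows = []
    for (_, cr), (_, cn), (_, so) in zip(climate_region.iterrows(),
                                         climate_nation.iterrows(),
                                         socio.iterrows()):
        npp_r = npp_thornthwaite(cr["tmp"], cr["pre"])
        npp_n = npp_thornthwaite(cn["tmp"], cn["pre"])
        s = biomass_factor(npp_r, npp_n)

        urban_r = _as_fraction(so["urban_rate_region"], "urban_rate_region")
        urban_n = _as_fraction(so["urban_rate_nation"], "urban_rate_nation")
        en_r = engel_composite(so["engel_rural_region"], so["engel_urban_region"],
                               1.0 - urban_r, urban_r)
        en_n = engel_composite(so["engel_rural_nation"], so["engel_urban_nation"],
                               1.0 - urban_n, urban_n)
        w_r = willingness_parameter(en_r)
        w_n = willingness_parameter(en_n)
        w_t = willingness_ratio(w_r, w_n)
        a_t = ability_ratio(so["gdp_region"], so["gdp_nation"])
        pi = socio_economic_factor(w_t, a_t)
        rows.append({"year": int(cr["year"]), "npp_region": npp_r,
                     "npp_nation": npp_n, "s": s, "en_region": en_r,
                     "en_nation": en_n, "w_region": w_r, "w_nation": w_n,
                     "w_t": w_t, "a_t": a_t, "pi": pi})
    return pd.DataFrame(rows)
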