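"""Climate indices defining the analysis domain, and reference PET.

The analysis is restricted to water-limited, vegetated land: pixels whose
dryness index (long-term fraction of months in which potential
evapotranspiration exceeds precipitation) is above 0.3 and whose NDVI
reaches at least 0.25 at some point in the record.

PET uses the FAO-56 reference-crop Penman-Monteith formulation (fixed
grass-surface albedo and resistances).  The forcing record carries no
humidity variable, so relative humidity enters as a configured parameter.
"""

from __future__ import annotations

import dataclasses

import numpy as np


def _sat_vapour_pressure(tair):
    """Saturation vapour pressure (kPa) at air temperature tair (degC)."""
    return 0.6108 * np.exp(17.27 * tair / (tair + 237.3))


def pet_penman_monteith(tair, net_radiation, wind, pressure,
                        rel_humidity=0.6, soil_heat_flux=0.0):
    """FAO-56 reference-crop evapotranspiration, mm/day.

    Parameters are scalars or broadcastable arrays: tair in degC,
    net_radiation and soil_heat_flux in MJ m-2 day-1, wind (2 m) in m/s,
    pressure in kPa, rel_humidity a fraction in [0, 1].

    ET0 = (0.408 D (Rn - G) + g * 900/(T+273) * u2 * (es - ea))
          / (D + g (1 + 0.34 u2))
    with D the slope of the saturation vapour-pressure curve and g the
    psychrometric constant 0.000665 * P.
    """
    tair = np.asarray(tair, dtype=float)
    rn = np.asarray(net_radiation, dtype=float)
    u2 = np.asarray(wind, dtype=float)
    p = np.asarray(pressure, dtype=float)
    for name, v in (("tair", tair), ("net_radiation", rn),
                    ("wind", u2), ("pressure", p)):
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite {name} in PET input")
    if (tair <= -40).any():
        raise ValueError("air temperature below -40 degC not supported")
    if (p <= 0).any():
        raise ValueError("surface pressure must be positive")
    es = _sat_vapour_pressure(tair)
    ea = rel_humidity * es
    delta = 4098.0 * es / (tair + 237.3) ** 2
    gamma = 0.000665 * p
    num = (0.408 * delta * (rn - soil_heat_flux)
           + gamma * (900.0 / (tair + 273.0)) * u2 * (es - ea))
    et0 = num / (delta + gamma * (1.0 + 0.34 * u2))
    et0 = np.maximum(et0, 0.0)
    return float(et0) if et0.ndim == 0 else et0


def dryness_index(pet_monthly, p_monthly) -> float:
    """Fraction of months in which mean PET strictly exceeds mean P.

    Both inputs are aligned climatological monthly means (>= 12 values).
    Ties (PET == P) do not count as exceedance.
    """
    pet_monthly = np.asarray(pet_monthly, dtype=float)
    p_monthly = np.asarray(p_monthly, dtype=float)
    if pet_monthly.shape != p_monthly.shape:
        raise ValueError("pet_monthly and p_monthly must have equal length")
    if pet_monthly.size < 12:
        raise ValueError("need at least 12 monthly values")
    return float(np.count_nonzero(pet_monthly > p_monthly) / pet_monthly.size)


def vegetation_mask(ndvi_series, threshold: float = 0.25) -> bool:
    """True (kept) unless max NDVI over the record is strictly below threshold."""
    a = np.asarray(ndvi_series, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("NDVI series is entirely missing")
    if np.asarray(ndvi_series).size < 12:
        raise ValueError("need at least 12 monthly NDVI values")
    return bool(a.max() >= threshold)


@dataclasses.dataclass(frozen=True)
class ClimateIndices:
    """Per-pixel domain diagnostics."""

    dryness: float
    max_ndvi: float
    in_domain: bool

    def __post_init__(self):
        if not 0.0 <= self.dryness <= 1.0:
            raise ValueError("dryness must lie in [0, 1]")


def classify_pixel(pet_monthly, p_monthly, ndvi_series,
                   dryness_threshold: float = 0.3,
                   ndvi_threshold: float = 0.25) -> ClimateIndices:
    """Apply the two-condition domain rule to one pixel."""
    d = dryness_index(pet_monthly, p_monthly)
    veg = vegetation_mask(ndvi_series, ndvi_threshold)
    max_ndvi = float(np.nanmax(np.asarray(ndvi_series, dtype=float)))
    return ClimateIndices(dryness=d, max_ndvi=max_ndvi,
                          in_domain=bool(d > dryness_threshold and veg))
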