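"""Synthetic truth twin and satellite-like observations.

Every downstream stage of the pipeline (assimilation, accessible-storage
inference, forecasting) is exercised on data generated here, so the module
encodes exactly the statistical structure the analysis assumes: monthly
greenness anomalies are a linear function of the anomaly of water storage
integrated over a hidden per-pixel depth class, lagged by a response lag,
plus Gaussian noise and a seasonal cycle.

Three observation streams mimic the satellite products the analysis is
designed around: daily noisy near-surface (0-5 cm) soil water, one noisy
monthly observation of the calendar-month mean of the daily column total,
and an 8-day surface-water fraction obtained through a saturating
transform of ponded surface water.

Everything is deterministic given (seed, pixel).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .climate import pet_penman_monteith
from .storage_inference import (DEPTH_CLASSES, integrate_storage,
                                monthly_anomalies, monthly_mean)
from .water_balance import ColumnParams, ColumnState, run_simulation

logger = logging.getLogger(__name__)

_STREAM_FORCING = 11
_STREAM_GREEN = 13
_STREAM_OBS = 17
_STREAM_MODEL = 19


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults describe a semi-arid pixel: ~500 mm/yr rain concentrated in a
    wet season, high evaporative demand, NDVI base 0.25 with seasonal
    amplitude 0.10 and a storage-driven anomaly of sd ~0.06 NDVI units.
    """

    n_pixels: int = 20
    n_years: int = 6
    seed: int = 0
    start: str = "2010-01-01"
    spinup_years: int = 2
    hidden_depth_classes: tuple | None = None   # per pixel; None -> cycle

    # greenness construction
    greenness_signal_sd: float = 0.06   # NDVI sd of the storage-driven term
    greenness_noise_sd: float = 0.012   # NDVI units
    response_lag: int = 1               # months
    ndvi_base: float = 0.25
    ndvi_seasonal_amp: float = 0.10

    # observation errors
    nearsurface_sd_range: tuple = (1.0, 2.0)    # mm
    column_sd_range: tuple = (10.0, 20.0)       # mm
    fraction_sd: float = 0.02
    nearsurface_gap_prob: float = 0.1
    sw_fraction_scale: float = 20.0             # mm, saturating transform

    # forcing generation
    precip_wet_prob: float = 0.25
    precip_wet_prob_seasonal: float = 0.15
    precip_gamma_shape: float = 0.8
    precip_mean_wet: float = 8.0        # mm on wet days
    precip_seasonal_amp: float = 0.5    # relative modulation of wet amounts
    tair_mean: float = 22.0
    tair_amp: float = 8.0
    tair_noise: float = 2.0
    rad_mean: float = 18.0
    rad_amp: float = 6.0
    rad_noise: float = 2.0
    wind_mean: float = 2.0
    pressure: float = 95.0
    rel_humidity: float = 0.6

    # degraded forcing product handed to the assimilation model
    model_precip_bias: float = 0.75
    model_precip_noise_sd: float = 0.6   # lognormal sigma, daily
    model_tair_offset: float = 1.0

    def __post_init__(self):
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (3-segment hindcast)")
        for name in ("greenness_signal_sd", "greenness_noise_sd",
                     "fraction_sd", "nearsurface_gap_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nearsurface_sd_range", "column_sd_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative range")
        if self.hidden_depth_classes is not None:
            bad = set(self.hidden_depth_classes) - set(DEPTH_CLASSES)
            if bad:
                raise ValueError(f"unknown depth classes: {bad}")

    def hidden_class(self, pixel: int) -> str:
        if self.hidden_depth_classes is not None:
            return self.hidden_depth_classes[pixel % len(self.hidden_depth_classes)]
        return DEPTH_CLASSES[pixel % len(DEPTH_CLASSES)]

    def rng(self, pixel: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(pixel), int(stream)]))


def _dates(config: SyntheticConfig, with_spinup: bool) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start)
    if with_spinup:
        start = start - pd.DateOffset(years=config.spinup_years)
    end = (pd.Timestamp(config.start) + pd.DateOffset(years=config.n_years)
           - pd.Timedelta(days=1))
    return pd.date_range(start, end, freq="D")


def generate_forcings(config: SyntheticConfig, pixel: int,
                      with_spinup: bool = False) -> pd.DataFrame:
    """Daily forcing series for one pixel (canonical forcing frame).

    Precipitation is a seasonally modulated mixture of dry days and
    Gamma-distributed wet amounts; temperature and radiation are seasonal
    sinusoids plus Gaussian noise; wind, pressure and (zero) snowfall are
    simple.  Deterministic given (config.seed, pixel).
    """
    dates = _dates(config, with_spinup)
    doy = dates.dayofyear.to_numpy()
    phase = np.sin(2 * np.pi * (doy - 15) / 365.25)   # wet season ~mid Jan

    wet_p = np.clip(config.precip_wet_prob
                    + config.precip_wet_prob_seasonal * phase, 0.0, 1.0)
    # draw uniforms/amounts for the full span so the study-period series is
    # identical whether or not spin-up days are prepended
    full = _dates(config, True)
    rng_full = config.rng(pixel, _STREAM_FORCING)
    u = rng_full.uniform(size=len(full))
    amounts = rng_full.gamma(config.precip_gamma_shape,
                             config.precip_mean_wet / config.precip_gamma_shape,
                             size=len(full))
    tnoise = rng_full.normal(0.0, 1.0, size=len(full))
    rnoise = rng_full.normal(0.0, 1.0, size=len(full))
    wnoise = rng_full.normal(0.0, 1.0, size=len(full))
    off = len(full) - len(dates)
    u, amounts = u[off:], amounts[off:]
    tnoise, rnoise, wnoise = tnoise[off:], rnoise[off:], wnoise[off:]

    seas_amount = 1.0 + config.precip_seasonal_amp * phase
    precip = np.where(u < wet_p, amounts * seas_amount, 0.0)
    tair = (config.tair_mean + config.tair_amp * phase
            + config.tair_noise * tnoise)
    rad = np.maximum(config.rad_mean + config.rad_amp * phase
                     + config.rad_noise * rnoise, 0.0)
    wind = np.maximum(config.wind_mean + 0.5 * wnoise, 0.1)
    df = pd.DataFrame({"precip": precip, "tair": tair, "rad": rad,
                       "wind": wind,
                       "pressure": np.full(len(dates), config.pressure),
                       "snow": np.zeros(len(dates))}, index=dates)
    return df


def pet_series(forcings: pd.DataFrame, rel_humidity: float) -> np.ndarray:
    """Daily reference PET for a forcing frame."""
    return pet_penman_monteith(forcings["tair"].to_numpy(),
                               forcings["rad"].to_numpy(),
                               forcings["wind"].to_numpy(),
                               forcings["pressure"].to_numpy(),
                               rel_humidity=rel_humidity)


def model_forcings(truth_forcings: pd.DataFrame,
                   config: SyntheticConfig, pixel: int) -> pd.DataFrame:
    """Degraded forcing product used by the assimilation/open-loop model.

    Emulates errors in a gridded precipitation product: a systematic bias
    factor plus independent daily lognormal amount noise, and a warm
    temperature offset.
    """
    rng = config.rng(pixel, _STREAM_MODEL)
    f = truth_forcings.copy()
    sigma = config.model_precip_noise_sd
    noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=len(f))
    f["precip"] = f["precip"].to_numpy() * config.model_precip_bias * noise
    f["tair"] = f["tair"].to_numpy() + config.model_tair_offset
    return f


def _seasonal_ndvi_climatology(config: SyntheticConfig) -> np.ndarray:
    m = np.arange(1, 13)
    # greenness peaks ~2 months after the wet-season peak
    return (config.ndvi_base
            + config.ndvi_seasonal_amp
            * np.sin(2 * np.pi * (m - 3.5) / 12.0))


@dataclasses.dataclass
class TruthPixel:
    """Truth twin for one pixel."""

    pixel: int
    hidden_class: str
    forcings: pd.DataFrame          # study period, daily
    pet: np.ndarray
    states: pd.DataFrame            # daily ColumnState fields, study period
    fluxes: pd.DataFrame
    greenness: pd.Series            # monthly absolute NDVI, PeriodIndex
    greenness_clim: np.ndarray      # 12 values
    storage_gain: float             # NDVI per mm of storage anomaly


def generate_truth(config: SyntheticConfig, pixel: int,
                   params: ColumnParams | None = None) -> TruthPixel:
    """Run the water-balance truth and derive greenness from it.

    Monthly greenness = seasonal climatology + a * (monthly anomaly of the
    storage integrated over the pixel's hidden depth class, lagged by the
    response lag) + Gaussian noise, clipped to [0, 1].  The gain a > 0 is
    set so the storage-driven term has sd ``greenness_signal_sd``.
    """
    params = params or ColumnParams()
    forcings_full = generate_forcings(config, pixel, with_spinup=True)
    pet_full = pet_series(forcings_full, config.rel_humidity)
    initial = ColumnState(s_top=5.0, s_shallow=50.0, s_deep=200.0,
                          groundwater=100.0)
    states_full, fluxes_full = run_simulation(initial, forcings_full,
                                              pet_full, params)
    start = pd.Timestamp(config.start)
    study = states_full.index >= start
    states = states_full.loc[study]
    fluxes = fluxes_full.loc[fluxes_full.index >= start]
    forcings = forcings_full.loc[forcings_full.index >= start]
    pet = pet_full[forcings_full.index >= start]

    # hidden-class storage anomalies over an extended window so that the
    # lagged predictor exists for the first study months
    ext = states_full.index >= (start - pd.DateOffset(months=config.response_lag + 1))
    s_monthly = monthly_mean(integrate_storage(states_full.loc[ext],
                                               config.hidden_class(pixel)))
    # anomalise against the study-period climatology only, matching the
    # downstream inference convention
    pre_study = [p for p in s_monthly.index if p < pd.Period(start, freq="M")]
    _, s_anom = monthly_anomalies(s_monthly, exclude_months=pre_study)

    months = pd.period_range(start, periods=config.n_years * 12, freq="M")
    lagged = s_anom.reindex(months - config.response_lag).to_numpy()
    sd = np.nanstd(lagged)
    gain = config.greenness_signal_sd / sd if sd > 0 else 0.0

    clim = _seasonal_ndvi_climatology(config)
    rng = config.rng(pixel, _STREAM_GREEN)
    noise = rng.normal(0.0, config.greenness_noise_sd, size=len(months))
    values = clim[months.month - 1] + gain * lagged + noise
    greenness = pd.Series(np.clip(values, 0.0, 1.0), index=months)
    return TruthPixel(pixel=pixel, hidden_class=config.hidden_class(pixel),
                      forcings=forcings, pet=pet, states=states,
                      fluxes=fluxes, greenness=greenness,
                      greenness_clim=clim, storage_gain=gain)


@dataclasses.dataclass
class ObservationSet:
    """Satellite-like observations for one pixel.

    near_surface: daily (date, value mm, error_sd mm);
    column_total: monthly (month Period, value mm, error_sd mm), the value
    being a noisy calendar-month mean of the daily column total;
    surface_fraction: 8-day (date, value in [0,1], error_sd).
    """

    near_surface: pd.DataFrame
    column_total: pd.DataFrame
    surface_fraction: pd.DataFrame

    def validate(self):
        if len(self.column_total):
            if self.column_total["month"].duplicated().any():
                raise ValueError("column_total must have at most one record per month")
            if (self.column_total["error_sd"] <= 0).any():
                raise ValueError("error sds must be > 0")
        if len(self.surface_fraction):
            v = self.surface_fraction["value"]
            if ((v < 0) | (v > 1)).any():
                raise ValueError("surface fractions must lie in [0, 1]")

    @classmethod
    def empty(cls):
        return cls(pd.DataFrame(columns=["date", "value", "error_sd"]),
                   pd.DataFrame(columns=["month", "value", "error_sd"]),
                   pd.DataFrame(columns=["date", "value", "error_sd"]))


def surface_fraction_transform(sw, scale: float):
    """Saturating map from ponded water (mm) to areal water fraction."""
    return 1.0 - np.exp(-np.asarray(sw, dtype=float) / scale)


def surface_fraction_inverse(frac, scale: float):
    """Inverse of the saturating transform, clipped away from fraction 1."""
    f = np.clip(np.asarray(frac, dtype=float), 0.0, 0.999)
    return -scale * np.log(1.0 - f)


def simulate_observations(states: pd.DataFrame, config: SyntheticConfig,
                          pixel: int) -> ObservationSet:
    """Sample the three observation streams from a truth trajectory.

    Per-record error sds are drawn from the configured ranges, emulating
    spatially/temporally varying product uncertainties.  A trailing partial
    calendar month yields no column observation (logged).
    """
    rng = config.rng(pixel, _STREAM_OBS)
    st = states
    dates = pd.DatetimeIndex(st.index)

    # near-surface: daily s_top with gaps
    sds = rng.uniform(*config.nearsurface_sd_range, size=len(st))
    vals = st["s_top"].to_numpy() + rng.normal(0.0, 1.0, len(st)) * sds
    keep = rng.uniform(size=len(st)) >= config.nearsurface_gap_prob
    near = pd.DataFrame({"date": dates, "value": vals, "error_sd": sds})[keep]

    # column total: calendar-month mean of the daily total
    total = st[["surface_water", "s_top", "s_shallow", "s_deep",
                "groundwater"]].sum(axis=1)
    periods = dates.to_period("M")
    counts = pd.Series(1, index=periods).groupby(level=0).sum()
    complete = counts[counts == counts.index.days_in_month].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        logger.warning("dropping partial month(s) %s from column observations",
                       list(dropped.astype(str)))
    mmean = pd.Series(total.to_numpy(), index=periods).groupby(level=0).mean()
    mmean = mmean[mmean.index.isin(complete)]
    csds = rng.uniform(*config.column_sd_range, size=len(mmean))
    col = pd.DataFrame({"month": mmean.index,
                        "value": mmean.to_numpy()
                        + rng.normal(0.0, 1.0, len(mmean)) * csds,
                        "error_sd": csds})

    # surface-water fraction every 8 days
    idx8 = np.arange(0, len(st), 8)
    frac = surface_fraction_transform(st["surface_water"].to_numpy()[idx8],
                                      config.sw_fraction_scale)
    fvals = np.clip(frac + rng.normal(0.0, config.fraction_sd, len(idx8)),
                    0.0, 1.0)
    sw = pd.DataFrame({"date": dates[idx8], "value": fvals,
                       "error_sd": np.full(len(idx8), config.fraction_sd)})
    obs = ObservationSet(near_surface=near.reset_index(drop=True),
                         column_total=col, surface_fraction=sw)
    obs.validate()
    return obs
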